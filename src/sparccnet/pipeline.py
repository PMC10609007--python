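"""End-to-end orchestration: counts → correlations → networks → comparison.

A run takes one count table with a sample→group map (or a synthetic-generation
block), estimates a SparCC correlation matrix per group, thresholds each into
a co-occurrence network, computes betweenness z-values, Louvain communities
and keystones, and finishes with the cross-group statistics: keystone
neighbor-match percentages, community counts, and hierarchical dendrograms of
group feature vectors and per-keystone edge profiles.  Every output lands in
one directory together with the effective configuration and a JSON manifest,
and a re-run with the same config and seed reproduces the numbers exactly.
"""

from __future__ import annotations

import configparser
import json
import logging
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .compare import (
    GroupNetworkSet,
    count_communities,
    edge_profile_vector,
    group_feature_vector,
    hierarchical_dendrogram,
    keystone_match_percent,
)
from .datasets import DIET_GROUPS, diet_study_zvalues
from .io import CountTable, read_count_table, read_group_map, relative_abundance
from .network import analyze_network
from .simulate import paper_scale_truth, plant_correlation_network, simulate_count_table
from .sparcc import sparcc_estimate

__all__ = ["PipelineConfig", "run_pipeline", "generate_fixture"]

logger = logging.getLogger("sparccnet")

_SMALL_N_WARNING = 20  # SparCC is noisy below this many samples per group


@dataclass
class PipelineConfig:
    """Every knob of a run; defaults match the module-level defaults."""

    # [input]  (either counts_path or synthetic=True)
    counts_path: str | None = None
    groups_path: str | None = None
    dialect: str = "tsv"
    # [synthetic]
    synthetic: bool = False
    n_taxa: int = 55
    n_modules: int = 3
    hub_count: int = 2
    within_rho: float = 0.7
    hub_rho: float = 0.6
    rewire_fraction: float = 0.4
    n_per_group: int = 5
    depth: int = 30_000
    group_names: tuple[str, ...] = DIET_GROUPS
    # [sparcc]
    n_resamples: int = 20
    exclusion_threshold: float = 0.1
    max_exclusions: int = 10
    aggregation: str = "median"
    fraction_mode: str = "dirichlet"
    seed: int = 0
    # [network]
    threshold: float = 0.3
    sign_mode: str = "absolute"
    distance_mode: str = "unweighted"
    louvain_weight: str = "unweighted"
    # [compare]
    match_denominator: str = "union"
    node_feature: str = "z_value"
    linkage: str = "average"
    # [output]
    output_dir: str = "sparccnet_out"

    _SECTIONS = {
        "input": ("counts_path", "groups_path", "dialect"),
        "synthetic": (
            "synthetic", "n_taxa", "n_modules", "hub_count", "within_rho",
            "hub_rho", "rewire_fraction", "n_per_group", "depth", "group_names",
        ),
        "sparcc": (
            "n_resamples", "exclusion_threshold", "max_exclusions",
            "aggregation", "fraction_mode", "seed",
        ),
        "network": ("threshold", "sign_mode", "distance_mode", "louvain_weight"),
        "compare": ("match_denominator", "node_feature", "linkage"),
        "output": ("output_dir",),
    }

    def validate(self) -> None:
        if not self.synthetic and self.counts_path is None:
            raise ValueError("config needs either counts_path or synthetic=true")

    # flat key/value text with sections, for diffable manifests
    def to_ini(self, path: str | Path) -> None:
        cp = configparser.ConfigParser()
        for section, keys in self._SECTIONS.items():
            cp[section] = {}
            for k in keys:
                v = getattr(self, k)
                if v is None:
                    continue
                cp[section][k] = ",".join(v) if isinstance(v, tuple) else str(v)
        with open(path, "w", encoding="utf-8") as fh:
            cp.write(fh)

    @classmethod
    def from_ini(cls, path: str | Path) -> "PipelineConfig":
        cp = configparser.ConfigParser()
        read = cp.read(path)
        if not read:
            raise FileNotFoundError(path)
        kwargs = {}
        defaults = cls()
        for section, keys in cls._SECTIONS.items():
            if section not in cp:
                continue
            for k in keys:
                if k not in cp[section]:
                    continue
                raw = cp[section][k]
                default = getattr(defaults, k)
                if isinstance(default, bool):
                    kwargs[k] = raw.strip().lower() in {"1", "true", "yes", "on"}
                elif isinstance(default, int):
                    kwargs[k] = int(raw)
                elif isinstance(default, float):
                    kwargs[k] = float(raw)
                elif isinstance(default, tuple):
                    kwargs[k] = tuple(s.strip() for s in raw.split(",") if s.strip())
                else:
                    kwargs[k] = raw
        return cls(**kwargs)


def _load_or_simulate(cfg: PipelineConfig):
    if cfg.synthetic:
        bases = paper_scale_truth(
            seed=cfg.seed,
            D=cfg.n_taxa,
            n_modules=cfg.n_modules,
            hub_count=cfg.hub_count,
            within_rho=cfg.within_rho,
            hub_rho=cfg.hub_rho,
            rewire_fraction=cfg.rewire_fraction,
            groups=tuple(cfg.group_names),
        )
        table, truth = simulate_count_table(
            bases, n_per_group=cfg.n_per_group, depth=cfg.depth, seed=cfg.seed
        )
        return table, truth
    table = read_count_table(cfg.counts_path, dialect=cfg.dialect)
    if cfg.groups_path:
        table.group_of = read_group_map(cfg.groups_path)
    return table, None


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and return the manifest (also written as JSON)."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_ini(out / "config.ini")
    logger.info("effective configuration written to %s", out / "config.ini")

    stage = "input"
    try:
        table, truth = _load_or_simulate(config)
        if truth is not None:
            with open(out / "synthetic_truth.json", "w", encoding="utf-8") as fh:
                json.dump(truth.to_json_dict(), fh)
            table.to_tsv(out / "counts.tsv")

        groups = table.groups()
        manifest: dict = {
            "version": __version__,
            "seed": config.seed,
            "groups": {},
            "files": ["config.ini"],
            "warnings": [],
        }
        frac = relative_abundance(table)
        phylum_of = {t.raw: (t.phylum or "") for t in table.taxa}

        nets, reports, keystone_union = {}, {}, []
        for gi, (g, sample_ids) in enumerate(groups.items()):
            stage = f"sparcc[{g}]"
            if len(sample_ids) < _SMALL_N_WARNING:
                msg = (
                    f"group {g!r} has only {len(sample_ids)} samples; SparCC "
                    f"correlation estimates are noisy below n={_SMALL_N_WARNING}"
                )
                warnings.warn(msg, UserWarning, stacklevel=2)
                manifest["warnings"].append(msg)
            sub = table.subset_samples(sample_ids)
            gseed = config.seed + 101 * gi  # per-group stream, stays < 2**31
            est = sparcc_estimate(
                sub,
                n_resamples=config.n_resamples,
                seed=gseed,
                aggregation=config.aggregation,
                exclusion_threshold=config.exclusion_threshold,
                max_exclusions=config.max_exclusions,
                fraction_mode=config.fraction_mode,
            )
            est.to_tsv(out / f"correlation_{g}.tsv")
            est.write_metadata(out / f"correlation_{g}.meta.json")

            stage = f"network[{g}]"
            net, rep = analyze_network(
                est,
                threshold=config.threshold,
                mode=config.sign_mode,
                seed=gseed,
                distance_mode=config.distance_mode,
                louvain_weight=config.louvain_weight,
            )
            cols = [table.samples.index(s) for s in sample_ids]
            mean_abund = {
                t.raw: float(frac[i, cols].mean()) for i, t in enumerate(table.taxa)
            }
            for n in net.graph.nodes:
                net.graph.nodes[n]["phylum"] = phylum_of.get(n, "")
                net.graph.nodes[n]["abundance"] = mean_abund.get(n, 0.0)
            net.to_graphml(out / f"network_{g}.graphml")
            net.to_edge_tsv(out / f"edges_{g}.tsv")
            rep.to_tsv(
                out / f"nodes_{g}.tsv",
                extra={"phylum": phylum_of, "abundance": mean_abund},
            )
            nets[g], reports[g] = net, rep
            ks = sorted(rep.keystones())
            keystone_union.extend(k for k in ks if k not in keystone_union)
            manifest["groups"][g] = {
                "n_samples": len(sample_ids),
                "seed": gseed,
                "n_edges": net.n_edges,
                "keystones": ks,
                "modularity": rep.modularity,
                "n_communities": rep.n_communities(),
                "n_communities_displayed": count_communities(
                    rep, scope="displayed_subset", abundance=mean_abund
                ),
            }
            manifest["files"] += [
                f"correlation_{g}.tsv", f"correlation_{g}.meta.json",
                f"network_{g}.graphml", f"edges_{g}.tsv", f"nodes_{g}.tsv",
            ]

        stage = "compare"
        net_set = GroupNetworkSet(networks=nets, reports=reports)
        with open(out / "keystone_match.tsv", "w", encoding="utf-8", newline="\n") as fh:
            fh.write("group\tkeystone_a\tkeystone_b\tintersection\tunion\tpercent\tdenominator\n")
            for g, rep in reports.items():
                ks = sorted(rep.keystones())
                for i, a in enumerate(ks):
                    for b in ks[i + 1:]:
                        m = keystone_match_percent(
                            nets[g], a, b, denominator=config.match_denominator, group=g
                        )
                        fh.write(
                            f"{g}\t{a}\t{b}\t{m.intersection_size}\t{m.union_size}\t"
                            f"{m.percent:.10g}\t{m.denominator}\n"
                        )
        manifest["files"].append("keystone_match.tsv")

        with open(out / "community_counts.tsv", "w", encoding="utf-8", newline="\n") as fh:
            fh.write("group\tall_nodes\tdisplayed_subset\n")
            for g in reports:
                fh.write(
                    f"{g}\t{manifest['groups'][g]['n_communities']}\t"
                    f"{manifest['groups'][g]['n_communities_displayed']}\n"
                )
        manifest["files"].append("community_counts.tsv")

        dendrograms = []
        if len(reports) >= 2:
            vecs = {
                g: group_feature_vector(net_set, g, node_feature=config.node_feature)
                for g in reports
            }
            tree = hierarchical_dendrogram(vecs, linkage=config.linkage)
            (out / "dendrogram_all.nwk").write_text(tree.to_newick() + "\n", encoding="utf-8")
            dendrograms.append("dendrogram_all.nwk")
            for ki, taxon in enumerate(keystone_union):
                profs = {g: edge_profile_vector(net_set, taxon, g) for g in reports}
                tree = hierarchical_dendrogram(profs, linkage=config.linkage)
                name = f"dendrogram_keystone_{ki}.nwk"
                (out / name).write_text(tree.to_newick() + "\n", encoding="utf-8")
                dendrograms.append(name)
        manifest["keystone_dendrogram_taxa"] = keystone_union
        manifest["files"] += dendrograms
        manifest["n_dendrograms"] = len(dendrograms)

        with open(out / "manifest.json", "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        manifest["files"].append("manifest.json")
        return manifest
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage}: {exc}") from exc


def generate_fixture(preset: str, seed: int = 0, output_dir: str | Path = "fixture") -> list[Path]:
    """Write a self-contained test fixture to disk.

    ``tiny`` is 12 taxa × 4 samples × 2 groups (runs in seconds);
    ``paper_scale`` is 55 taxa × 5 samples × 5 groups with planted keystone
    hubs.  Both include the worked-example z-value table
    (9 taxa × 5 groups) as a static TSV.
    """
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    if preset == "tiny":
        base = plant_correlation_network(12, 2, hub_count=1, within_rho=0.7,
                                         hub_rho=0.6, seed=seed)
        bases = {"ND": base, "WD": base}
        table, truth = simulate_count_table(bases, n_per_group=4, depth=5000, seed=seed)
    elif preset == "paper_scale":
        bases = paper_scale_truth(seed=seed)
        table, truth = simulate_count_table(bases, n_per_group=5, depth=30_000, seed=seed)
    else:
        raise ValueError(f"unknown preset {preset!r}")
    files = []
    table.to_tsv(out / "counts.tsv")
    files.append(out / "counts.tsv")
    with open(out / "groups.tsv", "w", encoding="utf-8", newline="\n") as fh:
        fh.write("sample\tgroup\n")
        for s in table.samples:
            fh.write(f"{s}\t{table.group_of[s]}\n")
    files.append(out / "groups.tsv")
    with open(out / "truth.json", "w", encoding="utf-8") as fh:
        json.dump(truth.to_json_dict(), fh)
    files.append(out / "truth.json")
    diet_study_zvalues().to_csv(out / "zvalue_table.tsv", sep="\t")
    files.append(out / "zvalue_table.tsv")
    return files
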