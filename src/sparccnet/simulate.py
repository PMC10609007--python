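"""Synthetic microbiome count tables with known correlation structure.

The generator plants the structure the downstream pipeline is meant to
recover: block-correlated modules of taxa (communities), hub taxa with many
strong cross-module correlations (keystone candidates), and group-specific
rewiring of the correlation pattern.  Counts arise from the generative model
under which the SparCC estimator is consistent — multivariate log-normal
basis abundances, closed to fractions, read out as multinomial counts — so
recovery tests against the planted truth are meaningful.

Defaults mirror the study design this package re-implements: 5 diet groups of
5 mice, ~55 genus-level taxa, ~3×10^4 reads per sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import CountTable, TaxonLabel

__all__ = [
    "BasisCovariance",
    "SyntheticTruth",
    "plant_correlation_network",
    "perturb_covariance",
    "simulate_count_table",
    "paper_scale_truth",
]

_PSD_TOL = 1e-10
_EIG_FLOOR = 1e-8

# pools of plausible mouse-gut genus labels in the rank-prefixed 16S style
_PHYLA = {
    "Firmicutes": [
        ("Lachnospiraceae", ["Blautia", "Roseburia", "[Ruminococcus]", "Dorea", ""]),
        ("Ruminococcaceae", ["Oscillospira", "Ruminococcus", "Faecalibacterium"]),
        ("Clostridiaceae", ["Clostridium", "SMB53", ""]),
        ("Lactobacillaceae", ["Lactobacillus"]),
        ("Staphylococcaceae", ["Staphylococcus"]),
        ("Erysipelotrichaceae", ["Allobaculum", "Coprobacillus"]),
        ("Dehalobacteriaceae", ["Dehalobacterium"]),
        ("Turicibacteraceae", ["Turicibacter"]),
    ],
    "Bacteroidetes": [
        ("S24-7", [""]),
        ("Bacteroidaceae", ["Bacteroides"]),
        ("[Paraprevotellaceae]", ["[Prevotella]"]),
        ("Prevotellaceae", ["Prevotella"]),
        ("Porphyromonadaceae", ["Parabacteroides"]),
        ("Rikenellaceae", ["AF12", ""]),
    ],
    "Proteobacteria": [
        ("Desulfovibrionaceae", ["Desulfovibrio", ""]),
        ("Alcaligenaceae", ["Sutterella"]),
        ("Enterobacteriaceae", ["Escherichia"]),
        ("Helicobacteraceae", ["Flexispira"]),
    ],
}


def synthetic_taxonomy(n: int) -> list[TaxonLabel]:
    """Deterministic list of ``n`` distinct rank-prefixed taxonomy labels."""
    pool: list[str] = []
    for phylum, families in _PHYLA.items():
        for family, genera in families:
            for genus in genera:
                pool.append(f"p_{phylum}; f_{family}; g_{genus}")
    k = 0
    while len(pool) < n:  # overflow beyond the named pool
        phylum = list(_PHYLA)[k % len(_PHYLA)]
        pool.append(f"p_{phylum}; f_Family{k:02d}; g_Genus{k:02d}")
        k += 1
    return [TaxonLabel.parse(s) for s in pool[:n]]


@dataclass
class BasisCovariance:
    """Planted covariance of log basis abundances for one group.

    ``planted_correlation`` is the exact block+hub design before any
    positive-semidefinite repair; ``correlation`` (and ``matrix``, the
    covariance actually sampled from) are its repaired versions.  The two
    coincide whenever the design is already PSD.
    """

    taxa: list[TaxonLabel]
    matrix: np.ndarray                      # D×D covariance (repaired, PSD)
    correlation: np.ndarray                 # D×D correlation of `matrix`
    planted_correlation: np.ndarray         # exact pre-repair design
    planted_modules: list[list[int]]        # partition of range(D)
    planted_hubs: list[int]
    within_rho: float
    log_variances: np.ndarray               # diagonal of `matrix`

    def __post_init__(self) -> None:
        D = len(self.taxa)
        for name in ("matrix", "correlation", "planted_correlation"):
            m = np.asarray(getattr(self, name), dtype=float)
            if m.shape != (D, D):
                raise ValueError(f"{name} must be {D}x{D}")
            if not np.allclose(m, m.T, atol=1e-12):
                raise ValueError(f"{name} is not symmetric")
            setattr(self, name, m)
        seen = sorted(i for mod in self.planted_modules for i in mod)
        if seen != list(range(D)):
            raise ValueError("planted_modules must partition the taxa exactly once each")

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    def module_of(self) -> np.ndarray:
        out = np.empty(self.n_taxa, dtype=int)
        for m, members in enumerate(self.planted_modules):
            out[members] = m
        return out


@dataclass
class SyntheticTruth:
    """Everything a recovery test needs: the generative state of one table."""

    basis: dict[str, BasisCovariance]       # group label → basis
    group_assignments: dict[str, str]       # sample id → group label
    seed: int
    depth: int

    def derived_true_correlation(self, group: str) -> np.ndarray:
        return self.basis[group].correlation

    def to_json_dict(self) -> dict:
        return {
            "seed": self.seed,
            "depth": self.depth,
            "groups": {
                g: {
                    "taxa": [t.raw for t in b.taxa],
                    "planted_modules": b.planted_modules,
                    "planted_hubs": b.planted_hubs,
                    "within_rho": b.within_rho,
                    "correlation": b.correlation.tolist(),
                }
                for g, b in self.basis.items()
            },
            "group_assignments": self.group_assignments,
        }


def _nearest_psd_correlation(corr: np.ndarray) -> np.ndarray:
    """Clip negative eigenvalues to a small floor and renormalize the diagonal."""
    vals, vecs = np.linalg.eigh(corr)
    if vals.min() >= -_PSD_TOL:
        return corr
    vals = np.clip(vals, _EIG_FLOOR, None)
    repaired = (vecs * vals) @ vecs.T
    d = np.sqrt(np.diag(repaired))
    repaired = repaired / np.outer(d, d)
    np.fill_diagonal(repaired, 1.0)
    return (repaired + repaired.T) / 2.0


def _covariance_from_correlation(corr: np.ndarray, log_variances: np.ndarray) -> np.ndarray:
    s = np.sqrt(log_variances)
    return corr * np.outer(s, s)


def plant_correlation_network(
    D: int,
    n_modules: int,
    hub_count: int = 0,
    within_rho: float = 0.6,
    hub_rho: float = 0.6,
    seed: int = 0,
    taxa: list[TaxonLabel] | None = None,
) -> BasisCovariance:
    """Build a block+hub correlation design and its (repaired) covariance.

    Taxa are split into ``n_modules`` near-equal contiguous blocks with
    pairwise correlation ``within_rho`` inside each block and 0 across blocks.
    ``hub_count`` taxa (one per module, round-robin) are additionally tied to
    every taxon outside their own module at ``hub_rho``, so each hub touches
    at least half of all taxa whenever ``n_modules >= 2``.  Log-variances are
    drawn uniformly in [0.5, 2].
    """
    if D <= 0 or n_modules < 1 or D < n_modules:
        raise ValueError("need D >= n_modules >= 1 with positive D")
    if hub_count < 0 or hub_count >= D:
        raise ValueError("hub_count must be in [0, D)")
    if not (0 <= within_rho < 1):
        raise ValueError("within_rho must lie in [0, 1)")
    if hub_count and not (0 < hub_rho < 1):
        raise ValueError("hub_rho must lie in (0, 1)")
    rng = np.random.default_rng(seed)

    bounds = np.linspace(0, D, n_modules + 1).astype(int)
    modules = [list(range(bounds[m], bounds[m + 1])) for m in range(n_modules)]

    corr = np.eye(D)
    for members in modules:
        idx = np.ix_(members, members)
        block = np.full((len(members), len(members)), within_rho)
        np.fill_diagonal(block, 1.0)
        corr[idx] = block

    module_of = np.empty(D, dtype=int)
    for m, members in enumerate(modules):
        module_of[members] = m

    hubs: list[int] = []
    for h in range(hub_count):
        members = modules[h % n_modules]
        # pick an unused member of the module as hub
        candidates = [i for i in members if i not in hubs]
        hub = int(rng.choice(candidates)) if candidates else int(rng.integers(D))
        hubs.append(hub)
    for hub in hubs:
        outside = np.flatnonzero(module_of != module_of[hub])
        corr[hub, outside] = hub_rho
        corr[outside, hub] = hub_rho

    planted = corr.copy()
    repaired = _nearest_psd_correlation(corr)
    log_var = rng.uniform(0.5, 2.0, size=D)
    cov = _covariance_from_correlation(repaired, log_var)
    return BasisCovariance(
        taxa=taxa if taxa is not None else synthetic_taxonomy(D),
        matrix=cov,
        correlation=repaired,
        planted_correlation=planted,
        planted_modules=modules,
        planted_hubs=hubs,
        within_rho=within_rho,
        log_variances=log_var,
    )


def perturb_covariance(
    basis: BasisCovariance, rewire_fraction: float, seed: int = 0, strong: float = 0.1
) -> BasisCovariance:
    """Rewire a fraction of the strong correlations to fresh taxon pairs.

    A ``rewire_fraction`` of the off-diagonal entries with |rho| > ``strong``
    (in the planted design) is zeroed, and an equal number of previously-zero
    pairs is set to the basis's module correlation; PSD repair is then
    re-applied.  Emulates group-specific network rewiring between diet groups.
    """
    if not (0.0 <= rewire_fraction <= 1.0):
        raise ValueError("rewire_fraction must lie in [0, 1]")
    if rewire_fraction == 0.0:
        return basis
    rng = np.random.default_rng(seed)
    D = basis.n_taxa
    planted = basis.planted_correlation.copy()
    iu = np.triu_indices(D, k=1)
    vals = planted[iu]
    strong_pos = np.flatnonzero(np.abs(vals) > strong)
    zero_pos = np.flatnonzero(vals == 0.0)
    n_rewire = int(round(rewire_fraction * strong_pos.size))
    n_rewire = min(n_rewire, strong_pos.size, zero_pos.size)
    drop = rng.choice(strong_pos, size=n_rewire, replace=False)
    add = rng.choice(zero_pos, size=n_rewire, replace=False)
    new_rho = basis.within_rho if basis.within_rho > 0 else 0.6
    vals = vals.copy()
    vals[drop] = 0.0
    vals[add] = new_rho
    planted[iu] = vals
    planted[(iu[1], iu[0])] = vals

    repaired = _nearest_psd_correlation(planted)
    cov = _covariance_from_correlation(repaired, basis.log_variances)
    return BasisCovariance(
        taxa=list(basis.taxa),
        matrix=cov,
        correlation=repaired,
        planted_correlation=planted,
        planted_modules=[list(m) for m in basis.planted_modules],
        planted_hubs=list(basis.planted_hubs),
        within_rho=basis.within_rho,
        log_variances=basis.log_variances,
    )


def simulate_count_table(
    basis: BasisCovariance | dict[str, BasisCovariance],
    n_per_group: int = 5,
    depth: int = 30_000,
    seed: int = 0,
) -> tuple[CountTable, SyntheticTruth]:
    """Draw a multinomial count table from log-normal basis abundances.

    For every sample: log basis abundances ~ MVN(0, group covariance);
    exponentiate; close to fractions (which sum to 1 exactly); draw
    ``depth`` multinomial reads.  Column sums therefore equal ``depth``.
    Identical ``seed`` and parameters reproduce the table bit for bit.
    """
    if depth < 100:
        raise ValueError("depth must be at least 100 reads per sample")
    if n_per_group < 2:
        raise ValueError("need at least 2 samples per group")
    bases = {"all": basis} if isinstance(basis, BasisCovariance) else dict(basis)
    first = next(iter(bases.values()))
    taxa = first.taxa
    for g, b in bases.items():
        if [t.raw for t in b.taxa] != [t.raw for t in taxa]:
            raise ValueError(f"group {g!r} has a different taxon list")
        if np.linalg.eigvalsh(b.matrix).min() < -1e-8:
            raise ValueError(f"group {g!r}: covariance not PSD after repair")

    rng = np.random.default_rng(seed)
    samples: list[str] = []
    group_of: dict[str, str] = {}
    columns: list[np.ndarray] = []
    for g, b in bases.items():
        # sqrt factor via eigh: deterministic and tolerant of tiny eigenvalues
        vals, vecs = np.linalg.eigh(b.matrix)
        factor = vecs * np.sqrt(np.clip(vals, 0.0, None))
        for j in range(n_per_group):
            z = factor @ rng.standard_normal(b.n_taxa)
            w = np.exp(z - z.max())  # overflow-safe; closure removes the shift
            frac = w / w.sum()
            counts = rng.multinomial(depth, frac)
            sid = f"{g}_{j + 1}"
            samples.append(sid)
            group_of[sid] = g
            columns.append(counts)
    table = CountTable(
        taxa=list(taxa),
        samples=samples,
        counts=np.column_stack(columns).astype(np.int64),
        group_of=group_of,
    )
    truth = SyntheticTruth(basis=bases, group_assignments=group_of, seed=seed, depth=depth)
    return table, truth


def paper_scale_truth(
    seed: int = 0,
    D: int = 55,
    n_modules: int = 3,
    hub_count: int = 2,
    within_rho: float = 0.7,
    hub_rho: float = 0.6,
    rewire_fraction: float = 0.4,
    groups: tuple[str, ...] = ("ND", "WD", "PC", "PG", "CG"),
) -> dict[str, BasisCovariance]:
    """Five diet-group bases: a reference design plus group-specific rewiring.

    The first group keeps the reference block+hub design; each later group
    rewires ``rewire_fraction`` of the strong correlations with its own seed,
    emulating the diet-specific network differences the study reports.
    """
    base = plant_correlation_network(
        D, n_modules, hub_count=hub_count, within_rho=within_rho, hub_rho=hub_rho, seed=seed
    )
    out = {groups[0]: base}
    for k, g in enumerate(groups[1:], start=1):
        out[g] = perturb_covariance(base, rewire_fraction, seed=seed + 1000 + k)
    return out
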