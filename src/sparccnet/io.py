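"""Count-table I/O, taxonomy labels, abundance summaries and clinical formulas.

The universal input of the pipeline is a taxon-by-sample table of non-negative
integer read counts whose row labels are taxonomy strings in the rank-prefixed
style common to 16S pipelines, e.g. ``"f_Lachnospiraceae; g_[Ruminococcus]"``.
Tables are read/written as UTF-8 TSV (first column ``taxonomy``, one column per
sample) and BIOM v1.0 JSON tables are accepted read-only.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "TaxonLabel",
    "CountTable",
    "read_count_table",
    "read_group_map",
    "relative_abundance",
    "abundance_ratio",
    "friedewald_ldl",
    "homa_ir",
]


_RANK_PREFIX = re.compile(r"^([a-zA-Z])_+(.*)$", re.DOTALL)

# canonical single-letter rank codes of the Greengenes/QIIME lineage style
_RANK_NAMES = {
    "k": "kingdom",
    "p": "phylum",
    "c": "class",
    "o": "order",
    "f": "family",
    "g": "genus",
    "s": "species",
}


@dataclass(frozen=True)
class TaxonLabel:
    """A taxonomy row label, kept verbatim plus parsed rank fields.

    ``raw`` is preserved exactly so that parse → serialize round-trips the
    input byte for byte.  An empty rank after its prefix (``"f_S24-7; g_"``)
    parses to the empty string, never to a missing field: genus-less labels
    are meaningful and must survive.  A bare ``"_"`` token (as in
    ``"f_Lachnospiraceae;_"``) is read as an empty genus.
    """

    raw: str
    ranks: dict = field(default_factory=dict, compare=False, hash=False)

    def __hash__(self) -> int:  # identity is the verbatim string
        return hash(self.raw)

    @classmethod
    def parse(cls, raw: str) -> "TaxonLabel":
        ranks: dict[str, str] = {}
        for token in raw.split(";"):
            token = token.strip()
            if not token:
                continue
            if set(token) == {"_"}:  # bare "_" → empty genus slot
                ranks.setdefault("genus", "")
                continue
            m = _RANK_PREFIX.match(token)
            if m and m.group(1).lower() in _RANK_NAMES:
                ranks[_RANK_NAMES[m.group(1).lower()]] = m.group(2).strip()
            else:
                ranks.setdefault("unranked", token)
        return cls(raw=raw, ranks=ranks)

    @property
    def phylum(self) -> str | None:
        return self.ranks.get("phylum")

    @property
    def family(self) -> str | None:
        return self.ranks.get("family")

    @property
    def genus(self) -> str | None:
        return self.ranks.get("genus")

    def __str__(self) -> str:
        return self.raw


class FormatError(ValueError):
    """Malformed input table (ragged rows, duplicates, bad cells)."""


@dataclass
class CountTable:
    """Taxon-by-sample non-negative integer counts with taxonomy labels.

    Parameters
    ----------
    taxa : list of TaxonLabel
        Row labels, unique by raw string.
    samples : list of str
        Column labels, unique.
    counts : ndarray of shape (n_taxa, n_samples)
        Non-negative integers.
    group_of : dict, optional
        Sample id → group label.
    """

    taxa: list[TaxonLabel]
    samples: list[str]
    counts: np.ndarray
    group_of: dict[str, str] | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2 or self.counts.shape != (len(self.taxa), len(self.samples)):
            raise FormatError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.taxa)} taxa x {len(self.samples)} samples"
            )
        if np.issubdtype(self.counts.dtype, np.floating):
            if not np.all(np.isfinite(self.counts)) or np.any(self.counts != np.round(self.counts)):
                raise FormatError("counts must be integral")
            self.counts = self.counts.astype(np.int64)
        if np.any(self.counts < 0):
            raise FormatError("counts must be non-negative")
        raws = [t.raw for t in self.taxa]
        if len(set(raws)) != len(raws):
            dup = sorted({r for r in raws if raws.count(r) > 1})
            raise FormatError(f"duplicate taxon labels: {dup[:3]}")
        if len(set(self.samples)) != len(self.samples):
            raise FormatError("duplicate sample ids")

    # ------------------------------------------------------------------ shape
    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def taxon_index(self, label: str | TaxonLabel) -> int:
        raw = label.raw if isinstance(label, TaxonLabel) else label
        for i, t in enumerate(self.taxa):
            if t.raw == raw:
                return i
        raise KeyError(f"taxon not in table: {raw!r}")

    def groups(self) -> dict[str, list[str]]:
        """Group label → sample ids, in table order."""
        if self.group_of is None:
            return {"all": list(self.samples)}
        out: dict[str, list[str]] = {}
        for s in self.samples:
            out.setdefault(self.group_of.get(s, "all"), []).append(s)
        return out

    def subset_samples(self, sample_ids: list[str]) -> "CountTable":
        idx = [self.samples.index(s) for s in sample_ids]
        return CountTable(
            taxa=list(self.taxa),
            samples=list(sample_ids),
            counts=self.counts[:, idx].copy(),
            group_of=None if self.group_of is None else {s: self.group_of[s] for s in sample_ids},
        )

    # -------------------------------------------------------------------- I/O
    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write("taxonomy\t" + "\t".join(self.samples) + "\n")
            for t, row in zip(self.taxa, self.counts):
                fh.write(t.raw + "\t" + "\t".join(str(int(c)) for c in row) + "\n")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=[t.raw for t in self.taxa], columns=self.samples)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CountTable":
        path = Path(path)
        with open(path, encoding="utf-8") as fh:
            lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
        if not lines:
            raise FormatError(f"{path}: empty table")
        header = lines[0].split("\t")
        samples = header[1:]
        if not samples:
            raise FormatError(f"{path}: line 1: no sample columns")
        taxa: list[TaxonLabel] = []
        rows: list[list[int]] = []
        for lineno, ln in enumerate(lines[1:], start=2):
            cells = ln.split("\t")
            if len(cells) != len(header):
                raise FormatError(
                    f"{path}: line {lineno}: expected {len(header)} columns, got {len(cells)}"
                )
            taxa.append(TaxonLabel.parse(cells[0]))
            try:
                row = [int(c) for c in cells[1:]]
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: non-integer count ({exc})") from exc
            if any(c < 0 for c in row):
                raise FormatError(f"{path}: line {lineno}: negative count")
            rows.append(row)
        if not rows:
            raise FormatError(f"{path}: table has a header but no taxon rows")
        return cls(taxa=taxa, samples=samples, counts=np.array(rows, dtype=np.int64))

    @classmethod
    def from_biom_json(cls, path: str | Path) -> "CountTable":
        """Read a BIOM v1.0 (JSON) table; both sparse and dense payloads."""
        path = Path(path)
        with open(path, encoding="utf-8") as fh:
            doc = json.load(fh)
        try:
            taxa = [TaxonLabel.parse(r["id"]) for r in doc["rows"]]
            samples = [c["id"] for c in doc["columns"]]
            shape = tuple(doc["shape"])
            mat = np.zeros(shape, dtype=np.float64)
            if doc.get("matrix_type", "sparse") == "dense":
                mat[:] = np.asarray(doc["data"], dtype=np.float64)
            else:
                for i, j, v in doc["data"]:
                    mat[int(i), int(j)] = v
        except (KeyError, TypeError, ValueError) as exc:
            raise FormatError(f"{path}: not a BIOM v1.0 JSON table ({exc})") from exc
        return cls(taxa=taxa, samples=samples, counts=mat)

    # -------------------------------------------------------------- summaries
    def collapse(self, rank: str = "genus") -> "CountTable":
        """Sum counts over taxa sharing the same label at ``rank``.

        Taxa lacking the rank keep their raw label as their own bucket.
        """
        buckets: dict[str, np.ndarray] = {}
        order: list[str] = []
        for t, row in zip(self.taxa, self.counts):
            key = t.ranks.get(rank)
            key = t.raw if not key else key
            if key not in buckets:
                buckets[key] = row.astype(np.int64).copy()
                order.append(key)
            else:
                buckets[key] += row
        return CountTable(
            taxa=[TaxonLabel.parse(k) for k in order],
            samples=list(self.samples),
            counts=np.vstack([buckets[k] for k in order]),
            group_of=self.group_of,
        )


def read_count_table(path: str | Path, dialect: str = "tsv") -> CountTable:
    """Read a count table; ``dialect`` is ``"tsv"`` or ``"biom-json"``."""
    if dialect == "tsv":
        return CountTable.from_tsv(path)
    if dialect == "biom-json":
        return CountTable.from_biom_json(path)
    raise ValueError(f"unknown dialect {dialect!r}; expected 'tsv' or 'biom-json'")


def read_group_map(path: str | Path) -> dict[str, str]:
    """Read a two-column sample→group TSV (no header required)."""
    out: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, ln in enumerate(fh, start=1):
            if not ln.strip():
                continue
            cells = ln.rstrip("\n").split("\t")
            if len(cells) != 2:
                raise FormatError(f"{path}: line {lineno}: expected 2 columns")
            if lineno == 1 and cells[0].lower() in {"sample", "sample_id", "#sample"}:
                continue
            out[cells[0]] = cells[1]
    return out


def relative_abundance(table: CountTable) -> np.ndarray:
    """Per-sample fractions: each column of the result sums to 1.

    Raises on a zero-total sample (a fraction is undefined there).
    """
    totals = table.counts.sum(axis=0)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        raise ValueError(f"sample(s) with zero total count: {[table.samples[i] for i in zero]}")
    return table.counts / totals.astype(np.float64)


def _match_taxa(table: CountTable, labels) -> np.ndarray:
    wanted = {l.raw if isinstance(l, TaxonLabel) else str(l) for l in labels}
    idx = np.array([i for i, t in enumerate(table.taxa) if t.raw in wanted], dtype=int)
    return idx


def abundance_ratio(table: CountTable, numerator_taxa, denominator_taxa) -> np.ndarray:
    """Pooled-fraction ratio per sample, e.g. Firmicutes/Bacteroidetes.

    The numerator and denominator fractions are summed over their taxon sets
    before dividing (phylum-style aggregation).  A sample whose pooled
    denominator is zero yields ``nan`` rather than a silent infinity.
    """
    num_idx = _match_taxa(table, numerator_taxa)
    den_idx = _match_taxa(table, denominator_taxa)
    if num_idx.size == 0 or den_idx.size == 0:
        raise ValueError("numerator or denominator taxon set matches no table rows")
    frac = relative_abundance(table)
    num = frac[num_idx].sum(axis=0)
    den = frac[den_idx].sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)
    return ratio


def taxa_with_rank(table: CountTable, rank: str, value: str) -> list[TaxonLabel]:
    """All table taxa whose parsed ``rank`` equals ``value`` (e.g. a phylum)."""
    return [t for t in table.taxa if t.ranks.get(rank) == value]


# --------------------------------------------------------------- serum indices
def friedewald_ldl(t_cho: float, hdl: float, tg: float) -> float:
    """Friedewald LDL-cholesterol estimate, mg/dL: T-Cho − HDL-c − TG/5."""
    if t_cho < 0 or hdl < 0 or tg < 0:
        raise ValueError("serum concentrations must be non-negative")
    return t_cho - hdl - tg / 5.0


def homa_ir(glucose: float, insulin: float) -> float:
    """HOMA-IR insulin-resistance index: fasting glucose × fasting insulin / 405."""
    if glucose < 0 or insulin < 0:
        raise ValueError("glucose and insulin must be non-negative")
    return glucose * insulin / 405.0
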