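"""Sample x taxon read tables: parsing, replicate merging, accumulation curves.

The central exchange object is :class:`ReadMatrix`, a thin wrapper around a
pandas integer count table (rows = samples, columns = taxa) plus a metadata
frame carrying the carrier (tick / vole), biotope (forest / ecotone) and sex
of every sample.  Sequencing produces two PCR replicates per sample; a taxon
counts as detected only when both replicates are positive, in which case the
replicate reads are summed (:func:`merge_replicates`).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

METADATA_COLUMNS = ("carrier", "biotope", "sex")

CARRIERS = ("tick", "vole")
BIOTOPES = ("forest", "ecotone")


@dataclasses.dataclass
class SampleRecord:
    """One biological sample with its read counts."""

    sample_id: str
    carrier: str
    biotope: str
    sex: str
    counts: dict[str, int]


@dataclasses.dataclass
class ReadMatrix:
    """Samples x taxa count table with per-sample metadata.

    Attributes
    ----------
    counts
        Integer DataFrame indexed by sample_id, one column per taxon.
    meta
        DataFrame indexed by sample_id with columns ``carrier``, ``biotope``,
        ``sex`` (extra metadata columns are preserved).
    taxon_rank
        One of ``{"OTU", "genus", "family", "order"}``.
    """

    counts: pd.DataFrame
    meta: pd.DataFrame
    taxon_rank: str = "genus"

    def __post_init__(self) -> None:
        if not self.counts.index.equals(self.meta.index):
            raise ValueError("counts and meta must share the same sample index")
        if self.counts.index.has_duplicates:
            dups = self.counts.index[self.counts.index.duplicated()].unique()
            raise ValueError(f"duplicate sample_id(s): {list(dups)}")
        if self.counts.columns.has_duplicates:
            raise ValueError("duplicate taxon columns")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative read counts")

    # -- basic views ---------------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def taxa(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def total_reads(self) -> int:
        return int(self.counts.to_numpy().sum())

    def presence(self) -> pd.DataFrame:
        """Boolean detection matrix (reads > 0)."""
        return self.counts > 0

    def subset(self, carrier: str | None = None, biotope: str | None = None) -> "ReadMatrix":
        """Restrict to one stratum; taxa columns are kept (possibly all-zero)."""
        mask = pd.Series(True, index=self.meta.index)
        if carrier is not None:
            mask &= self.meta["carrier"] == carrier
        if biotope is not None:
            mask &= self.meta["biotope"] == biotope
        return ReadMatrix(self.counts.loc[mask].copy(), self.meta.loc[mask].copy(), self.taxon_rank)

    def to_records(self) -> list[SampleRecord]:
        return [
            SampleRecord(
                sample_id=str(sid),
                carrier=str(self.meta.at[sid, "carrier"]),
                biotope=str(self.meta.at[sid, "biotope"]),
                sex=str(self.meta.at[sid, "sex"]),
                counts={t: int(c) for t, c in row.items() if c > 0},
            )
            for sid, row in self.counts.iterrows()
        ]

    @classmethod
    def from_records(
        cls,
        records: Iterable[SampleRecord],
        taxa: Sequence[str] | None = None,
        taxon_rank: str = "genus",
    ) -> "ReadMatrix":
        records = list(records)
        if taxa is None:
            seen: dict[str, None] = {}
            for r in records:
                for t in r.counts:
                    seen.setdefault(t, None)
            taxa = list(seen)
        counts = pd.DataFrame(
            [[int(r.counts.get(t, 0)) for t in taxa] for r in records],
            index=pd.Index([r.sample_id for r in records], name="sample_id"),
            columns=list(taxa),
            dtype=np.int64,
        )
        meta = pd.DataFrame(
            {
                "carrier": [r.carrier for r in records],
                "biotope": [r.biotope for r in records],
                "sex": [r.sex for r in records],
            },
            index=counts.index,
        )
        return cls(counts, meta, taxon_rank)


def read_table(
    path: str | Path,
    metadata_columns: Sequence[str] = METADATA_COLUMNS,
    taxon_rank: str = "genus",
    sep: str | None = None,
) -> ReadMatrix:
    """Read a TSV/CSV sample x taxon table.

    The first column must be ``sample_id``; ``metadata_columns`` follow; every
    remaining column is a taxon whose cells are nonnegative integer read
    counts.  Blank cells are read as 0.  Non-integer counts raise a
    ``ValueError`` naming the offending row and column.
    """
    path = Path(path)
    if sep is None:
        sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, dtype=str)
    if "sample_id" not in df.columns:
        raise ValueError(f"{path}: missing 'sample_id' column")
    missing = [c for c in metadata_columns if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing metadata column(s) {missing}")
    if df["sample_id"].duplicated().any():
        dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"{path}: duplicate sample_id(s) {dups}")
    df = df.set_index("sample_id")
    meta = df[list(metadata_columns)].fillna("unknown")
    taxon_cols = [c for c in df.columns if c not in metadata_columns]
    parsed: dict[str, list[int]] = {}
    for col in taxon_cols:
        vals = []
        for sid, cell in df[col].items():
            s = "" if cell is None or (isinstance(cell, float) and np.isnan(cell)) else str(cell).strip()
            try:
                val = int(s) if s else 0  # blank cell -> 0
            except ValueError:
                raise ValueError(
                    f"{path}: non-integer count {cell!r} at sample {sid!r}, taxon {col!r}"
                ) from None
            if val < 0:
                raise ValueError(f"{path}: negative count at sample {sid!r}, taxon {col!r}")
            vals.append(val)
        parsed[col] = vals
    counts = pd.DataFrame(parsed, index=df.index, dtype=np.int64)
    return ReadMatrix(counts, meta, taxon_rank)


def write_table(matrix: ReadMatrix, path: str | Path, sep: str | None = None) -> None:
    """Write a ReadMatrix as TSV/CSV (inverse of :func:`read_table`)."""
    path = Path(path)
    if sep is None:
        sep = "," if path.suffix.lower() == ".csv" else "\t"
    out = pd.concat([matrix.meta, matrix.counts], axis=1)
    out.index.name = "sample_id"
    out.to_csv(path, sep=sep)


def merge_replicates(rep_a: ReadMatrix, rep_b: ReadMatrix) -> ReadMatrix:
    """Merge two PCR replicates with the both-positive consistency rule.

    A sample is positive for a taxon only when *both* replicates have nonzero
    reads; positive cells are combined by adding the replicate read numbers,
    all other cells become 0.
    """
    if set(rep_a.sample_ids) != set(rep_b.sample_ids):
        raise ValueError("replicates have mismatched sample sets")
    if set(rep_a.taxa) != set(rep_b.taxa):
        raise ValueError("replicates have mismatched taxon sets")
    b_counts = rep_b.counts.loc[rep_a.counts.index, rep_a.counts.columns]
    both = (rep_a.counts > 0) & (b_counts > 0)
    merged = (rep_a.counts + b_counts).where(both, 0).astype(np.int64)
    return ReadMatrix(merged, rep_a.meta.copy(), rep_a.taxon_rank)


def aggregate_taxa(matrix: ReadMatrix, mapping: Mapping[str, str], rank: str = "genus") -> ReadMatrix:
    """Sum OTU columns into higher-rank taxa using an otu -> taxon mapping.

    OTUs absent from the mapping are dropped (unassigned at the target rank).
    """
    keep = [t for t in matrix.taxa if t in mapping]
    grouped = matrix.counts[keep].T.groupby(lambda otu: mapping[otu]).sum().T
    return ReadMatrix(grouped.astype(np.int64), matrix.meta.copy(), rank)


def _expected_richness(counts: np.ndarray, depth: int) -> float:
    """Expected distinct taxa when `depth` reads are drawn without replacement.

    Hypergeometric expectation: E = sum_t 1 - C(N - n_t, d) / C(N, d),
    evaluated with log-gamma for numerical safety.
    """
    n = int(counts.sum())
    if depth >= n:
        return float((counts > 0).sum())
    c = counts[counts > 0].astype(float)
    # log C(N - n_t, d) - log C(N, d)
    log_miss = (
        gammaln(n - c + 1)
        - gammaln(depth + 1)
        - gammaln(n - c - depth + 1)
        - (gammaln(n + 1) - gammaln(depth + 1) - gammaln(n - depth + 1))
    )
    with np.errstate(invalid="ignore"):
        p_miss = np.where(n - c >= depth, np.exp(log_miss), 0.0)
    return float(np.sum(1.0 - p_miss))


def accumulation_curve(
    matrix: ReadMatrix,
    sample_id: str,
    n_points: int = 20,
    seed: int | None = None,
    method: str = "analytic",
    n_draws: int = 1000,
) -> list[tuple[int, float]]:
    """Taxon accumulation (rarefaction) curve for one sample.

    Returns ``[(depth, expected distinct taxa), ...]`` on a grid of
    ``n_points`` subsampling depths from 1 to the sample's total reads,
    under subsampling without replacement.  ``method="analytic"`` uses the
    hypergeometric closed form; ``method="montecarlo"`` averages ``n_draws``
    random subsamples (the sampling oracle, reproducible under ``seed``).
    """
    if sample_id not in matrix.counts.index:
        raise KeyError(f"unknown sample {sample_id!r}")
    counts = matrix.counts.loc[sample_id].to_numpy()
    total = int(counts.sum())
    if total == 0:
        raise ValueError(f"sample {sample_id!r} has no reads")
    depths = np.unique(np.linspace(1, total, min(n_points, total)).round().astype(int))
    if method == "analytic":
        return [(int(d), _expected_richness(counts, int(d))) for d in depths]
    if method == "montecarlo":
        rng = np.random.default_rng(seed)
        pool = np.repeat(np.arange(len(counts)), counts)
        out = []
        for d in depths:
            hits = [len(np.unique(rng.choice(pool, size=int(d), replace=False))) for _ in range(n_draws)]
            out.append((int(d), float(np.mean(hits))))
        return out
    raise ValueError(f"unknown method {method!r}")
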