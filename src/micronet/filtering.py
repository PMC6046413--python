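"""Read-table filters applied before network construction.

Three rules, applied in a fixed order:

1. drop taxa not assigned at the target rank (``drop_unassigned``);
2. drop taxa detected in exactly one sample over the whole table
   (``drop_singletons``);
3. zero out occurrences whose read count falls strictly below a per-taxon
   cutoff — the 10th percentile of that taxon's nonzero read counts
   (``per_taxon_low_read_cutoff``).

The percentile is computed over *nonzero* counts with linear interpolation
between order statistics; zeros are non-detections, not low reads.
Occurrences equal to the cutoff are retained.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .sample_io import ReadMatrix


@dataclasses.dataclass
class FilterReport:
    """Audit trail of what each filter removed."""

    n_unassigned_removed: int = 0
    n_singletons_removed: int = 0
    per_taxon_cutoff: dict[str, float] = dataclasses.field(default_factory=dict)
    n_occurrences_zeroed: int = 0
    removed_unassigned: list[str] = dataclasses.field(default_factory=list)
    removed_singletons: list[str] = dataclasses.field(default_factory=list)

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


def drop_unassigned(matrix: ReadMatrix, assigned: set[str]) -> tuple[ReadMatrix, FilterReport]:
    """Remove taxa whose name is not in the assigned set."""
    keep = [t for t in matrix.taxa if t in assigned]
    dropped = [t for t in matrix.taxa if t not in assigned]
    out = ReadMatrix(matrix.counts[keep].copy(), matrix.meta.copy(), matrix.taxon_rank)
    report = FilterReport(n_unassigned_removed=len(dropped), removed_unassigned=dropped)
    return out, report


def drop_singletons(matrix: ReadMatrix) -> tuple[ReadMatrix, FilterReport]:
    """Remove taxa detected (reads > 0) in exactly one sample of the table."""
    n_pos = (matrix.counts > 0).sum(axis=0)
    dropped = [t for t in matrix.taxa if n_pos[t] == 1]
    keep = [t for t in matrix.taxa if n_pos[t] != 1]
    out = ReadMatrix(matrix.counts[keep].copy(), matrix.meta.copy(), matrix.taxon_rank)
    report = FilterReport(n_singletons_removed=len(dropped), removed_singletons=dropped)
    return out, report


def per_taxon_low_read_cutoff(
    matrix: ReadMatrix, percentile: float = 10.0, cutoffs: dict[str, float] | None = None
) -> tuple[ReadMatrix, FilterReport]:
    """Zero out occurrences below each taxon's low-read cutoff.

    The cutoff is *established once* per taxon: the given percentile
    (default 10) of the taxon's nonzero read counts across all samples,
    linearly interpolated.  Occurrences *strictly* below it are set to 0.
    Pass a previously established ``cutoffs`` map to re-apply the same
    filter (re-application with recorded cutoffs is a no-op; re-estimating
    on already-filtered data would ratchet the percentile upward).
    """
    if not 0 <= percentile < 100:
        raise ValueError("percentile must be in [0, 100)")
    counts = matrix.counts.copy()
    fixed = cutoffs
    cutoffs = {}
    zeroed = 0
    for taxon in matrix.taxa:
        col = counts[taxon].to_numpy()
        nonzero = col[col > 0]
        if nonzero.size == 0:
            cutoffs[taxon] = 0.0
            continue
        if fixed is not None:
            cutoff = float(fixed.get(taxon, 0.0))
        else:
            cutoff = float(np.percentile(nonzero, percentile, method="linear"))
        cutoffs[taxon] = cutoff
        mask = (col > 0) & (col < cutoff)
        zeroed += int(mask.sum())
        col[mask] = 0
        counts[taxon] = col
    out = ReadMatrix(counts, matrix.meta.copy(), matrix.taxon_rank)
    report = FilterReport(per_taxon_cutoff=cutoffs, n_occurrences_zeroed=zeroed)
    return out, report


def apply_filters(
    matrix: ReadMatrix,
    assigned: set[str] | None = None,
    percentile: float = 10.0,
    iterate: bool = False,
) -> tuple[ReadMatrix, FilterReport]:
    """Run the three filters in order: unassigned -> singletons -> cutoff.

    ``iterate=True`` re-applies singleton removal after the cutoff step until
    a fixed point (off by default; the default order applies each rule once).
    """
    report = FilterReport()
    if assigned is not None:
        matrix, r1 = drop_unassigned(matrix, assigned)
        report.n_unassigned_removed = r1.n_unassigned_removed
        report.removed_unassigned = r1.removed_unassigned
    matrix, r2 = drop_singletons(matrix)
    report.n_singletons_removed = r2.n_singletons_removed
    report.removed_singletons = r2.removed_singletons
    matrix, r3 = per_taxon_low_read_cutoff(matrix, percentile)
    report.per_taxon_cutoff = r3.per_taxon_cutoff
    report.n_occurrences_zeroed = r3.n_occurrences_zeroed
    while iterate:
        matrix, rs = drop_singletons(matrix)
        if rs.n_singletons_removed == 0:
            break
        report.n_singletons_removed += rs.n_singletons_removed
        report.removed_singletons += rs.removed_singletons
    return matrix, report


def presence(matrix: ReadMatrix) -> pd.DataFrame:
    """Boolean samples x taxa detection matrix (reads > 0 after filtering)."""
    return matrix.presence()
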