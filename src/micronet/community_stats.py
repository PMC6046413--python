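"""Assemblage-level summaries: Sørensen similarity, shared/exclusive genus
accounting, per-carrier-community richness and phylogenetic diversity, and
the Pareto-style concentration of PD in a minority of carriers.
"""

from __future__ import annotations

import dataclasses

import pandas as pd

from .carrier_network import CarrierNetwork
from .phylo_metrics import PhyloTree, faith_pd
from .sample_io import ReadMatrix


def sorensen(set_a, set_b) -> float:
    """Sørensen index 2|A∩B| / (|A|+|B|) on presence/absence sets.

    0 = totally dissimilar, 1 = identical composition.
    """
    A, B = set(set_a), set(set_b)
    if not A and not B:
        raise ValueError("both sets are empty")
    return 2.0 * len(A & B) / (len(A) + len(B))


def group_genus_sets(matrix: ReadMatrix) -> dict[tuple[str, str], set[str]]:
    """Pooled genus presence per (carrier, biotope) group."""
    pres = matrix.presence()
    out: dict[tuple[str, str], set[str]] = {}
    for (carrier, biotope), idx in matrix.meta.groupby(["carrier", "biotope"]).groups.items():
        detected = pres.loc[idx].any(axis=0)
        out[(carrier, biotope)] = set(detected.index[detected])
    return out


def sorensen_matrix(matrix: ReadMatrix) -> pd.DataFrame:
    """Pairwise Sørensen between the pooled (carrier, biotope) genus sets."""
    sets = group_genus_sets(matrix)
    keys = sorted(sets)
    names = [f"{c}_{b}" for c, b in keys]
    out = pd.DataFrame(1.0, index=names, columns=names)
    for i, ki in enumerate(keys):
        for j, kj in enumerate(keys):
            if i < j:
                s = sorensen(sets[ki], sets[kj])
                out.iloc[i, j] = out.iloc[j, i] = s
    return out


def shared_exclusive(matrix: ReadMatrix) -> dict:
    """Genus sharing between the two carriers, pooled over biotopes."""
    carriers = sorted(matrix.meta["carrier"].unique())
    if len(carriers) != 2:
        raise ValueError(f"need exactly 2 carriers, found {carriers}")
    pres = matrix.presence()
    sets = {}
    for carrier in carriers:
        idx = matrix.meta.index[matrix.meta["carrier"] == carrier]
        detected = pres.loc[idx].any(axis=0)
        sets[carrier] = set(detected.index[detected])
    c1, c2 = carriers
    shared = sets[c1] & sets[c2]
    total = sets[c1] | sets[c2]
    return {
        "carriers": (c1, c2),
        "n_shared": len(shared),
        f"n_only_{c1}": len(sets[c1] - sets[c2]),
        f"n_only_{c2}": len(sets[c2] - sets[c1]),
        "n_total": len(total),
        "pct_shared": 100.0 * len(shared) / len(total) if total else 0.0,
    }


@dataclasses.dataclass
class CommunitySummary:
    """One carrier community of the individual-similarity network."""

    label: int
    carrier: str
    n_individuals: int
    pct_individuals: float  # percent of this carrier's individuals in the biotope
    n_genera: int  # union of genera over members
    pd: float  # Faith's PD of that union
    mean_member_pd: float  # mean of per-individual Faith's PD


def summarize_communities(
    net: CarrierNetwork, presence: pd.DataFrame, tree: PhyloTree
) -> list[CommunitySummary]:
    """Per-community percent of carriers, genus richness and Faith's PD.

    Communities are summarised separately per carrier (a mixed community
    yields one row per carrier present in it); rows are sorted by
    decreasing pct_individuals within each carrier.
    """
    if net.communities is None:
        raise ValueError("run detect_carrier_communities first")
    carrier_totals: dict[str, int] = {}
    for sid in net.nodes:
        carrier_totals[net.carrier_of(sid)] = carrier_totals.get(net.carrier_of(sid), 0) + 1

    rows: list[CommunitySummary] = []
    by_comm: dict[int, list[str]] = {}
    for sid, lab in net.communities.items():
        by_comm.setdefault(lab, []).append(sid)
    for lab, members in sorted(by_comm.items()):
        for carrier in sorted({net.carrier_of(s) for s in members}):
            mine = [s for s in members if net.carrier_of(s) == carrier]
            union: set[str] = set()
            member_pds = []
            for sid in mine:
                row = presence.loc[sid]
                taxa = set(row.index[row])
                union |= taxa
                if taxa:
                    member_pds.append(faith_pd(tree, taxa))
            if not union:
                continue
            missing = union - {leaf.taxon.label for leaf in tree.leaf_node_iter()}
            if missing:
                raise KeyError(f"genera missing from tree: {sorted(missing)}")
            rows.append(
                CommunitySummary(
                    label=lab,
                    carrier=carrier,
                    n_individuals=len(mine),
                    pct_individuals=100.0 * len(mine) / carrier_totals[carrier],
                    n_genera=len(union),
                    pd=faith_pd(tree, union),
                    mean_member_pd=sum(member_pds) / len(member_pds) if member_pds else 0.0,
                )
            )
    rows.sort(key=lambda r: (r.carrier, -r.pct_individuals, r.label))
    return rows


def pd_concentration(summaries: list[CommunitySummary]) -> dict:
    """Largest community vs the rest: does a minority carry most of the PD?

    Splits the communities into the largest one (by pct_individuals) and all
    others; the minor communities' PDs are summed ("accumulated PD").  A
    ratio = accumulated minor PD / major PD well above 1 is the Pareto-style
    pattern in which ~20% of carriers circulate most of the phylogenetic
    diversity.  The PD of the pooled minor genus union is reported alongside.
    """
    if len(summaries) < 2:
        raise ValueError("need at least 2 communities")
    ordered = sorted(summaries, key=lambda r: -r.pct_individuals)
    major, minors = ordered[0], ordered[1:]
    minor_pd_sum = sum(m.pd for m in minors)
    return {
        "major_pct": major.pct_individuals,
        "major_pd": major.pd,
        "major_n_genera": major.n_genera,
        "minor_pct": sum(m.pct_individuals for m in minors),
        "minor_accumulated_pd": minor_pd_sum,
        "ratio": minor_pd_sum / major.pd if major.pd > 0 else float("inf"),
    }


def summaries_to_frame(summaries: list[CommunitySummary]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(s) for s in summaries])
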