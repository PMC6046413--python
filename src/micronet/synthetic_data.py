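"""Synthetic tick/vole microbiome data with known ground truth.

The generator emulates the statistical structure the downstream analysis
assumes: two carriers (tick, vole) sampled in two biotopes (forest,
ecotone); a fixed genus catalogue; latent "packets" of genera that always
co-occur within a sample (microorganisms circulating together); group-level
genus pools whose overlap is high across biotopes for the same carrier and
low between carriers; per-occurrence read depths drawn from a negative
binomial and truncated below at 1 (a present genus must be observable).

Default sizes mirror the field study the pipeline was designed around:
228/73 ticks and 177/92 voles in forest/ecotone, 126 genera, and a mean
per-sample richness of packets_per_sample x packet_size_mean +
noise_genus_rate = 1.5 x 8 + 1.4 = 13.4 genera.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import dendropy
import numpy as np

from .phylo_metrics import PhyloTree, shared_path_matrix, write_newick
from .sample_io import ReadMatrix, SampleRecord

Group = tuple[str, str]  # (carrier, biotope)

DEFAULT_GROUP_SIZES: dict[Group, int] = {
    ("tick", "forest"): 228,
    ("tick", "ecotone"): 73,
    ("vole", "forest"): 177,
    ("vole", "ecotone"): 92,
}


@dataclasses.dataclass
class SimConfig:
    """Parameters of the synthetic community generator.

    biotope_overlap / carrier_overlap are the probabilities that a packet
    (or free noise genus) is shared by both biotopes / both carriers; an
    overlap o yields an expected pool Sørensen of 2o/(1+o), so the defaults
    0.65 and 0.15 give ~0.79 across biotopes and ~0.26 between carriers.
    """

    n_genera: int = 126
    n_samples_per_group: dict[Group, int] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_GROUP_SIZES)
    )
    n_packets: int = 12
    packet_size_mean: float = 8.0
    packets_per_sample: tuple[int, int] = (1, 2)
    noise_genus_rate: float = 1.4
    biotope_overlap: float = 0.65
    carrier_overlap: float = 0.15
    nb_mean: float = 600.0
    nb_dispersion: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if self.n_genera < 1 or self.n_packets < 1:
            raise ValueError("n_genera and n_packets must be positive")
        if any(n < 1 for n in self.n_samples_per_group.values()):
            raise ValueError("all group sample counts must be positive")
        if self.packet_size_mean <= 0 or self.nb_mean <= 0 or self.nb_dispersion <= 0:
            raise ValueError("packet_size_mean, nb_mean, nb_dispersion must be positive")
        if self.noise_genus_rate < 0:
            raise ValueError("noise_genus_rate must be nonnegative")
        for name in ("biotope_overlap", "carrier_overlap"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        lo, hi = self.packets_per_sample
        if not (1 <= lo <= hi):
            raise ValueError("packets_per_sample must be a range with 1 <= lo <= hi")
        if hi > self.n_packets:
            raise ValueError("packets_per_sample exceeds n_packets")
        if self.n_packets * self.packet_size_mean > self.n_genera:
            raise ValueError(
                "packet construction impossible: "
                f"n_packets * packet_size_mean = {self.n_packets * self.packet_size_mean:g} "
                f"> n_genera = {self.n_genera}"
            )


@dataclasses.dataclass
class SimOutput:
    """Generated data plus the ground truth the tests recover."""

    read_matrix: ReadMatrix
    tree: PhyloTree
    packet_assignment: dict[str, int]
    group_pools: dict[Group, set[str]]


def _genus_names(n: int) -> list[str]:
    return [f"Genus_{i:03d}" for i in range(1, n + 1)]


def _assign_groups(rng: np.random.Generator, config: SimConfig) -> tuple[bool, bool, bool, bool]:
    """(forest, ecotone, tick, vole) membership flags for one item."""
    if rng.random() < config.biotope_overlap:
        forest = ecotone = True
    else:
        forest = rng.random() < 0.5
        ecotone = not forest
    if rng.random() < config.carrier_overlap:
        tick = vole = True
    else:
        tick = rng.random() < 0.5
        vole = not tick
    return forest, ecotone, tick, vole


def simulate_read_matrix(config: SimConfig) -> SimOutput:
    """Draw one synthetic dataset (reads, tree, ground truth) from a config.

    Per sample: 1..k packets are drawn without replacement from the sample's
    group packet pool, every genus of every chosen packet is present, plus
    Poisson(noise_genus_rate) free genera from the group pool; each present
    genus receives max(1, NegBin(nb_mean, nb_dispersion)) reads.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    genera = _genus_names(config.n_genera)

    # --- packets: disjoint genus blocks; sizes 1 + Poisson(mean - 1)
    sizes = 1 + rng.poisson(max(config.packet_size_mean - 1.0, 0.0), size=config.n_packets)
    while sizes.sum() > config.n_genera:  # trim the largest packets
        sizes[int(np.argmax(sizes))] -= 1
    packet_assignment: dict[str, int] = {}
    cursor = 0
    packet_members: list[list[str]] = []
    for p, size in enumerate(sizes):
        members = genera[cursor : cursor + int(size)]
        for g in members:
            packet_assignment[g] = p
        packet_members.append(members)
        cursor += int(size)
    free_genera = genera[cursor:]

    # --- assign packets and free genera to (carrier, biotope) pools.
    # Rejection sampling: redraw the whole packet assignment until every
    # sampled group holds enough packets, preserving the overlap semantics
    # exactly (in particular, overlap 0 keeps pools disjoint).
    groups = list(config.n_samples_per_group)
    lo, hi = config.packets_per_sample

    def place(item_groups, target, item):
        forest, ecotone, tick, vole = item_groups
        for carrier, biotope in groups:
            if ((biotope == "forest" and forest) or (biotope == "ecotone" and ecotone)) and (
                (carrier == "tick" and tick) or (carrier == "vole" and vole)
            ):
                target[(carrier, biotope)].append(item)

    for _attempt in range(1000):
        packet_pools: dict[Group, list[int]] = {g: [] for g in groups}
        for p in range(config.n_packets):
            place(_assign_groups(rng, config), packet_pools, p)
        if all(len(packet_pools[g]) >= hi for g in groups):
            break
    else:
        raise ValueError(
            "could not allot >= packets_per_sample packets to every sampled "
            "group; increase n_packets or the overlap fractions"
        )
    free_pools: dict[Group, list[str]] = {g: [] for g in groups}
    for g in free_genera:
        place(_assign_groups(rng, config), free_pools, g)

    group_pools: dict[Group, set[str]] = {
        grp: {g for p in packet_pools[grp] for g in packet_members[p]} | set(free_pools[grp])
        for grp in groups
    }

    # --- samples
    p_nb = config.nb_dispersion / (config.nb_dispersion + config.nb_mean)
    records: list[SampleRecord] = []
    for (carrier, biotope), n_samples in config.n_samples_per_group.items():
        pool_packets = packet_pools[(carrier, biotope)]
        pool_free = free_pools[(carrier, biotope)]
        for s in range(n_samples):
            k = int(rng.integers(lo, hi + 1))
            chosen = rng.choice(len(pool_packets), size=min(k, len(pool_packets)), replace=False)
            present = [g for c in chosen for g in packet_members[pool_packets[int(c)]]]
            m = int(rng.poisson(config.noise_genus_rate))
            candidates = [g for g in pool_free if g not in present]
            if m > 0 and candidates:
                noise_idx = rng.choice(len(candidates), size=min(m, len(candidates)), replace=False)
                present += [candidates[int(i)] for i in noise_idx]
            reads = np.maximum(1, rng.negative_binomial(config.nb_dispersion, p_nb, size=len(present)))
            records.append(
                SampleRecord(
                    sample_id=f"{carrier}_{biotope}_{s + 1:03d}",
                    carrier=carrier,
                    biotope=biotope,
                    sex="M" if rng.random() < 0.5 else "F",
                    counts={g: int(r) for g, r in zip(present, reads)},
                )
            )

    matrix = ReadMatrix.from_records(records, taxa=genera)
    tree = simulate_yule_tree(config.n_genera, seed=int(rng.integers(2**31 - 1)), labels=genera)
    return SimOutput(matrix, tree, packet_assignment, group_pools)


def simulate_yule_tree(
    n_tips: int, seed: int, birth_rate: float = 1.0, labels: list[str] | None = None
) -> PhyloTree:
    """Pure-birth (Yule) tree with ``n_tips`` labelled tips.

    Lineages split at rate ``birth_rate`` each; the splitting lineage is
    chosen uniformly.  All branch lengths are positive and the tree is
    reproducible bit-exactly under a fixed seed.
    """
    if n_tips < 2:
        raise ValueError("n_tips must be >= 2")
    if labels is None:
        labels = _genus_names(n_tips)
    if len(labels) != n_tips:
        raise ValueError("labels length must equal n_tips")
    rng = np.random.default_rng(seed)

    taxon_ns = dendropy.TaxonNamespace(labels)
    root = dendropy.Node()
    active: list[tuple[dendropy.Node, float]] = [(root, 0.0)]
    t = 0.0
    while len(active) < n_tips:
        k = len(active)
        t += rng.exponential(1.0 / (birth_rate * k))
        i = int(rng.integers(k))
        node, born = active.pop(i)
        node.edge.length = t - born if node.parent_node is not None else None
        left, right = dendropy.Node(), dendropy.Node()
        node.add_child(left)
        node.add_child(right)
        active.append((left, t))
        active.append((right, t))
    t_end = t + rng.exponential(1.0 / (birth_rate * n_tips))
    order = rng.permutation(n_tips)
    for (node, born), lab_i in zip(active, order):
        node.edge.length = t_end - born
        node.taxon = taxon_ns.get_taxon(labels[int(lab_i)])
    tree = dendropy.Tree(taxon_namespace=taxon_ns)
    tree.seed_node = root
    return tree


def simulate_bm_trait(
    tree: PhyloTree, lambda_true: float, sigma2: float, seed: int
) -> dict[str, float]:
    """One multivariate-normal trait under lambda-transformed Brownian motion.

    Covariance = sigma2 * C(lambda) where C holds shared root-to-MRCA path
    lengths and lambda multiplies the off-diagonal entries; lambda_true = 0
    gives independent tip values with variance sigma2 x tip depth.
    """
    if not 0.0 <= lambda_true <= 1.0:
        raise ValueError("lambda_true must be in [0, 1]")
    if sigma2 <= 0:
        raise ValueError("sigma2 must be positive")
    for edge in tree.preorder_edge_iter():
        if edge.head_node.parent_node is not None and edge.length is None:
            raise ValueError("tree has missing branch lengths")
    C = shared_path_matrix(tree)
    names = list(C.index)
    Cl = C.to_numpy() * lambda_true
    np.fill_diagonal(Cl, np.diag(C.to_numpy()))
    rng = np.random.default_rng(seed)
    L = np.linalg.cholesky(sigma2 * Cl + 1e-12 * np.eye(len(names)))
    y = L @ rng.standard_normal(len(names))
    return {name: float(v) for name, v in zip(names, y)}


def write_outputs(sim: SimOutput, out_dir: str | Path) -> None:
    """Write reads (TSV), tree (Newick) and ground truth (JSON) to a directory."""
    from .sample_io import write_table

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_table(sim.read_matrix, out_dir / "reads.tsv")
    (out_dir / "tree.nwk").write_text(write_newick(sim.tree) + "\n")
    truth = {
        "packet_assignment": sim.packet_assignment,
        "group_pools": {f"{c}|{b}": sorted(p) for (c, b), p in sim.group_pools.items()},
    }
    (out_dir / "ground_truth.json").write_text(json.dumps(truth, indent=2) + "\n")
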