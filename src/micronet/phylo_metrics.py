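"""Phylogenetic machinery: Newick trees, neighbor joining, Faith's PD, Pagel's lambda.

Trees are :class:`dendropy.Tree` objects throughout; tips are labelled by
bacterial genus.  Pagel's lambda measures the phylogenetic signal of a
continuous tip trait (prevalence, or a network index such as BNC/CC/PR)
under a Brownian-motion model whose off-diagonal tip covariances — the
shared root-to-MRCA path lengths — are multiplied by lambda in [0, 1]:
lambda near 0 means the trait is independent of the tree, lambda near 1
means full Brownian signal.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
from scipy import linalg, optimize

from .sample_io import ReadMatrix

PhyloTree = dendropy.Tree


# ---------------------------------------------------------------------------
# Newick I/O
# ---------------------------------------------------------------------------

def parse_newick(text: str) -> PhyloTree:
    """Parse a Newick string into a rooted tree with branch lengths."""
    try:
        return dendropy.Tree.get(data=text, schema="newick")
    except Exception as exc:  # dendropy raises several parse error types
        raise ValueError(f"malformed Newick: {exc}") from exc


def write_newick(tree: PhyloTree) -> str:
    return tree.as_string(schema="newick", suppress_rooting=True).strip()


def tip_labels(tree: PhyloTree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


# ---------------------------------------------------------------------------
# Shared-path (phylogenetic) covariance
# ---------------------------------------------------------------------------

def shared_path_matrix(tree: PhyloTree, labels: Sequence[str] | None = None) -> pd.DataFrame:
    """Tip covariance C under Brownian motion.

    C[i, i] is the root-to-tip path length of tip i; C[i, j] is the shared
    path length from the root to the MRCA of tips i and j.
    """
    tree = tree.clone(depth=1)
    tree.calc_node_root_distances(return_leaf_distances_only=False)
    leaves = list(tree.leaf_node_iter())
    names = [lf.taxon.label for lf in leaves]
    idx = {lf: i for i, lf in enumerate(leaves)}
    n = len(leaves)
    C = np.zeros((n, n))
    for lf in leaves:
        C[idx[lf], idx[lf]] = lf.root_distance
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            continue
        depth = node.root_distance or 0.0
        children = node.child_nodes()
        sets = [[idx[lf] for lf in ch.leaf_iter()] for ch in children]
        for a in range(len(sets)):
            for b in range(a + 1, len(sets)):
                for i in sets[a]:
                    for j in sets[b]:
                        C[i, j] = C[j, i] = depth
    df = pd.DataFrame(C, index=names, columns=names)
    if labels is not None:
        missing = [t for t in labels if t not in df.index]
        if missing:
            raise KeyError(f"taxa missing from tree: {missing}")
        df = df.loc[list(labels), list(labels)]
    return df


def patristic_distance_matrix(tree: PhyloTree) -> pd.DataFrame:
    """Pairwise tip-to-tip path lengths (d = depth_i + depth_j - 2*shared)."""
    C = shared_path_matrix(tree)
    depths = np.diag(C.to_numpy())
    D = depths[:, None] + depths[None, :] - 2.0 * C.to_numpy()
    np.fill_diagonal(D, 0.0)
    return pd.DataFrame(D, index=C.index, columns=C.columns)


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------

def neighbor_joining(dist: pd.DataFrame) -> PhyloTree:
    """Saitou–Nei neighbor joining from a symmetric distance matrix.

    For an additive matrix the tree's path lengths reproduce the input
    exactly.  Negative branch-length estimates are clamped to 0 with the
    deficit transferred to the sibling branch (flagged with a warning).
    Ties in the Q criterion break on the lexicographically first pair so the
    result is deterministic.
    """
    D = dist.to_numpy(dtype=float).copy()
    labels = list(dist.index)
    if D.shape[0] != D.shape[1] or list(dist.columns) != labels:
        raise ValueError("distance matrix must be square with matching labels")
    if D.shape[0] < 3:
        raise ValueError("need at least 3 taxa")
    if not np.allclose(D, D.T, atol=1e-8):
        raise ValueError("distance matrix must be symmetric")
    if np.any(np.diag(D) != 0):
        raise ValueError("distance matrix diagonal must be zero")

    taxon_ns = dendropy.TaxonNamespace(labels)
    nodes = [dendropy.Node(taxon=taxon_ns.get_taxon(l)) for l in labels]
    active = list(range(len(labels)))
    clamped = False

    while len(active) > 2:
        r = len(active)
        sub = D[np.ix_(active, active)]
        R = sub.sum(axis=1)
        Q = (r - 2) * sub - R[:, None] - R[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        ai, aj = min(
            (int(i), int(j))
            for i, j in np.argwhere(np.isclose(Q, qmin, rtol=0, atol=1e-9))
            if i < j
        )
        i, j = active[ai], active[aj]
        dij = D[i, j]
        li = 0.5 * dij + (R[ai] - R[aj]) / (2 * (r - 2))
        lj = dij - li
        if li < 0:
            lj += li
            li = 0.0
            clamped = True
        if lj < 0:
            li += lj
            lj = 0.0
            clamped = True
        parent = dendropy.Node()
        ei = parent.add_child(nodes[i])
        nodes[i].edge.length = li
        parent.add_child(nodes[j])
        nodes[j].edge.length = lj
        # distances from the new node to every other active node
        new_row = 0.5 * (D[i, :] + D[j, :] - dij)
        D = np.vstack([D, new_row])
        D = np.hstack([D, np.append(new_row, 0.0)[:, None]])
        nodes.append(parent)
        k = D.shape[0] - 1
        active = [a for a in active if a not in (i, j)] + [k]

    i, j = active
    d = D[i, j]
    if d < 0:
        d = 0.0
        clamped = True
    root = dendropy.Node()
    root.add_child(nodes[i])
    nodes[i].edge.length = d / 2
    root.add_child(nodes[j])
    nodes[j].edge.length = d / 2
    if clamped:
        warnings.warn("negative NJ branch length(s) clamped to 0 (deficit moved to sibling)")
    tree = dendropy.Tree(taxon_namespace=taxon_ns)
    tree.seed_node = root
    return tree


# ---------------------------------------------------------------------------
# Faith's phylogenetic diversity
# ---------------------------------------------------------------------------

def faith_pd(tree: PhyloTree, taxa) -> float:
    """Rooted Faith's PD: total branch length of the minimal subtree
    connecting the given tips *and* the root (a single tip contributes its
    root-to-tip path length)."""
    taxa = set(taxa)
    if not taxa:
        raise ValueError("taxa set is empty")
    tips = set(tip_labels(tree))
    missing = sorted(taxa - tips)
    if missing:
        raise KeyError(f"taxa missing from tree: {missing}")
    total = 0.0
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            node._pd_keep = node.taxon.label in taxa
        else:
            node._pd_keep = any(ch._pd_keep for ch in node.child_nodes())
        if node._pd_keep and node.parent_node is not None:
            total += node.edge.length or 0.0
    return total


# ---------------------------------------------------------------------------
# Pagel's lambda
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class LambdaFit:
    """Maximum-likelihood Pagel's lambda fit for one continuous tip trait."""

    lambda_hat: float
    loglik_at_hat: float
    loglik_at_0: float
    loglik_at_1: float
    sigma2_hat: float
    root_state_hat: float
    identifiable: bool = True
    n_tips: int = 0


def _lambda_loglik(lam: float, C: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Profile log-likelihood at a given lambda (root state and rate profiled
    out analytically by GLS)."""
    n = len(y)
    Cl = C * lam
    np.fill_diagonal(Cl, np.diag(C))
    cho = linalg.cho_factor(Cl, lower=True)
    ones = np.ones(n)
    Ci1 = linalg.cho_solve(cho, ones)
    Ciy = linalg.cho_solve(cho, y)
    beta = (ones @ Ciy) / (ones @ Ci1)
    resid = y - beta
    sigma2 = (resid @ linalg.cho_solve(cho, resid)) / n
    logdet = 2.0 * np.sum(np.log(np.diag(cho[0])))
    ll = -0.5 * (n * np.log(2 * np.pi * sigma2) + logdet + n)
    return float(ll), float(beta), float(sigma2)


def pagels_lambda(tree: PhyloTree, trait: Mapping[str, float], tol: float = 1e-6) -> LambdaFit:
    """Maximum-likelihood estimate of Pagel's lambda on [0, 1].

    The trait is modelled as multivariate normal with mean = root state and
    covariance sigma2 * C(lambda), where C(lambda) multiplies the
    off-diagonal shared-path entries of the Brownian covariance by lambda.
    Root state and sigma2 are profiled analytically (GLS) at each lambda;
    lambda is optimised by bounded scalar search, with the boundary fits at
    0 and 1 always evaluated.  A star tree (all shared paths zero) makes
    lambda unidentifiable and is flagged rather than returning an arbitrary
    interior optimum.
    """
    usable = [t for t in tip_labels(tree) if t in trait and np.isfinite(trait[t])]
    if len(usable) < 4:
        raise ValueError(f"need >= 4 tips with trait values, got {len(usable)}")
    C = shared_path_matrix(tree, usable).to_numpy()
    y = np.array([float(trait[t]) for t in usable])
    n = len(y)
    if np.max(np.diag(C)) <= 0:
        raise ValueError("tree has zero total depth")

    offdiag = C.copy()
    np.fill_diagonal(offdiag, 0.0)
    if np.max(np.abs(offdiag)) < 1e-12 * np.max(np.diag(C)):
        ll0, beta, sigma2 = _lambda_loglik(0.0, C, y)
        return LambdaFit(np.nan, ll0, ll0, ll0, sigma2, beta, identifiable=False, n_tips=n)

    def neg_ll(lam: float) -> float:
        return -_lambda_loglik(lam, C, y)[0]

    res = optimize.minimize_scalar(neg_ll, bounds=(0.0, 1.0), method="bounded",
                                   options={"xatol": tol})
    ll0 = _lambda_loglik(0.0, C, y)[0]
    ll1 = _lambda_loglik(1.0, C, y)[0]
    candidates = [(ll0, 0.0), (ll1, 1.0), (-res.fun, float(res.x))]
    ll_hat, lam_hat = max(candidates, key=lambda c: c[0])
    _, beta, sigma2 = _lambda_loglik(lam_hat, C, y)
    return LambdaFit(lam_hat, ll_hat, ll0, ll1, sigma2, beta, identifiable=True, n_tips=n)


def lambda_lrt_pvalue(fit: LambdaFit) -> float:
    """Likelihood-ratio p-value against lambda = 0 (chi2, 1 df)."""
    from scipy.stats import chi2

    stat = 2.0 * (fit.loglik_at_hat - fit.loglik_at_0)
    return float(chi2.sf(max(stat, 0.0), df=1))


# ---------------------------------------------------------------------------
# Traits
# ---------------------------------------------------------------------------

def prevalence(
    matrix: ReadMatrix, carrier: str | None = None, biotope: str | None = None
) -> dict[str, float]:
    """Per-genus detection fraction over the samples of one stratum."""
    sub = matrix.subset(carrier=carrier, biotope=biotope)
    if len(sub.sample_ids) == 0:
        raise ValueError(f"empty stratum carrier={carrier!r} biotope={biotope!r}")
    frac = sub.presence().mean(axis=0)
    return {t: float(frac[t]) for t in sub.taxa}


def read_distance_matrix(path) -> pd.DataFrame:
    """Read a square TSV distance matrix with a header row and index column."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.columns = [str(c) for c in df.columns]
    df.index = [str(i) for i in df.index]
    return df
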