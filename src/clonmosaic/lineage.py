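"""Early embryonic mutations, sample phylogeny and spatial lineage patterns.

Mosaic mutations shared at high allele frequency by more than two sampled
clones are classified as early (embryonic/ancestral) mutations: each
microdissected area is treated as one clone, so the carrier unit is the
sample. The sample phylogeny is a two-state (presence/absence) maximum-
likelihood tree: per-character pruning likelihood under a symmetric
binary-change model with a single shared branch length, exhaustive
topology search up to 7 leaves and a nearest-neighbour-interchange hill
climb from a neighbour-joining start above that.

First-generation lineages are the earliest mutually exclusive EEM clades;
their spatial arrangement is classified *layered* (lineage-pure vertical
layers alternating between adjacent layers), *mixed* (lineages interleaved
within layers with lateral asymmetry) or *indeterminate*, using Cramér's V
association scores between lineage label and each spatial axis.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.stats import chi2_contingency


# ---------------------------------------------------------------------------
# EEM detection

def detect_eems(
    case_variants: pd.DataFrame,
    min_carriers: int = 3,
    min_median_vaf: float = 0.2,
    carrier_min_alt: int = 2,
    carrier_min_vaf: float = 0.1,
    germline_min_vaf: float = 0.3,
    germline_carrier_frac: float = 0.9,
) -> pd.DataFrame:
    """Early-mutation candidates from one case's variant table.

    A mutation is an EEM when it is carried by more than two samples
    (``min_carriers`` = 3, the strict reading of "more than two clones"),
    its median carrier VAF reaches ``min_median_vaf`` (high-frequency,
    germline-resembling mosaic), and it is not present in every sample at
    germline-like VAF (germline proper is handled upstream). Returns one
    row per EEM with its carrier sample set.
    """
    n_samples = case_variants["sample_id"].nunique()
    if n_samples < 4:
        raise ValueError("EEM detection needs >= 4 samples in the case")
    vaf = case_variants["alt_count"] / case_variants["total_depth"]
    carrier = (case_variants["alt_count"] >= carrier_min_alt) & (vaf >= carrier_min_vaf)
    cdf = case_variants[carrier].copy()
    cdf["vaf"] = vaf[carrier]
    rows = []
    for vid, grp in cdf.groupby("variant_id", sort=True):
        k = grp["sample_id"].nunique()
        med = float(grp["vaf"].median())
        if k < min_carriers or med < min_median_vaf:
            continue
        if k >= germline_carrier_frac * n_samples and med >= germline_min_vaf:
            continue  # germline-like (near-)universal sharing, not mosaic
        rows.append(
            dict(
                variant_id=vid,
                n_carriers=k,
                median_vaf=med,
                carriers=frozenset(grp["sample_id"]),
            )
        )
    return pd.DataFrame(rows, columns=["variant_id", "n_carriers", "median_vaf", "carriers"])


# ---------------------------------------------------------------------------
# Two-state ML tree on an unrooted adjacency structure

@dataclass
class PhyloTree:
    """Unrooted binary tree over samples with a fitted shared branch length."""

    adjacency: dict  # node -> tuple of neighbours; leaves are sample names
    leaves: tuple
    branch_length: float = 0.1
    log_likelihood: float = float("nan")
    star: bool = False

    def splits(self) -> set[frozenset]:
        """Nontrivial bipartitions (as the smaller-side leaf sets are not
        canonical, each split is the frozenset of one side containing a
        fixed reference leaf's complement)."""
        out = set()
        ref = self.leaves[0]
        for u, nbrs in self.adjacency.items():
            for v in nbrs:
                if isinstance(u, int) and isinstance(v, int) and u < v:
                    side = _leafset_beyond(self.adjacency, v, u)
                    if 1 < len(side) < len(self.leaves) - 1:
                        if ref in side:
                            side = frozenset(set(self.leaves) - side)
                        out.add(frozenset(side))
        return out

    def newick(self) -> str:
        root = next(n for n in self.adjacency if isinstance(n, int))
        return _newick_from(self.adjacency, root, None, self.branch_length) + ";"


def _leafset_beyond(adj, start, blocked) -> frozenset:
    seen, stack, leaves = {blocked, start}, [start], []
    if not isinstance(start, int):
        return frozenset([start])
    while stack:
        n = stack.pop()
        for m in adj[n]:
            if m in seen:
                continue
            seen.add(m)
            if isinstance(m, int):
                stack.append(m)
            else:
                leaves.append(m)
    return frozenset(leaves)


def _newick_from(adj, node, parent, bl) -> str:
    if not isinstance(node, int):
        return f"{node}:{bl:.6g}"
    parts = [
        _newick_from(adj, m, node, bl) for m in adj[node] if m != parent
    ]
    inner = ",".join(parts)
    return f"({inner})" if parent is None else f"({inner}):{bl:.6g}"


def _pruning_loglik(adj, presence: pd.DataFrame, t: float) -> float:
    """Felsenstein pruning for a symmetric 2-state model, shared branch
    length t, stationary root frequencies (1/2, 1/2)."""
    p_change = 0.5 * (1.0 - np.exp(-2.0 * t))
    P = np.array([[1 - p_change, p_change], [p_change, 1 - p_change]])
    data = presence.to_numpy(dtype=int)  # samples x chars
    sample_idx = {s: i for i, s in enumerate(presence.index)}
    n_chars = data.shape[1]
    root = next(n for n in adj if isinstance(n, int))

    def partial(node, parent):
        if not isinstance(node, int):
            states = data[sample_idx[node]]
            L = np.zeros((n_chars, 2))
            L[np.arange(n_chars), states] = 1.0
            return L
        L = np.ones((n_chars, 2))
        for child in adj[node]:
            if child == parent:
                continue
            Lc = partial(child, node)
            L *= Lc @ P.T
        return L

    L_root = partial(root, None)
    site_lik = 0.5 * L_root.sum(axis=1)
    return float(np.log(np.maximum(site_lik, 1e-300)).sum())


def _optimize_branch(adj, presence) -> tuple[float, float]:
    res = minimize_scalar(
        lambda t: -_pruning_loglik(adj, presence, t),
        bounds=(1e-4, 5.0),
        method="bounded",
        options={"xatol": 1e-4},
    )
    return float(res.x), -float(res.fun)


def _enumerate_topologies(leaves):
    """All unrooted binary topologies by stepwise leaf addition."""
    leaves = list(leaves)
    first = {0: (leaves[0], leaves[1], leaves[2])}
    first[leaves[0]] = (0,)
    first[leaves[1]] = (0,)
    first[leaves[2]] = (0,)
    trees = [first]
    next_internal = 1
    for leaf in leaves[3:]:
        new_trees = []
        for adj in trees:
            edges = {
                tuple(sorted((u, v), key=str))
                for u, nbrs in adj.items()
                for v in nbrs
            }
            for u, v in sorted(edges, key=str):
                new = {k: list(vs) for k, vs in adj.items()}
                w = next_internal
                new[u] = [w if x == v else x for x in new[u]]
                new[v] = [w if x == u else x for x in new[v]]
                new[w] = [u, v, leaf]
                new[leaf] = [w]
                new_trees.append({k: tuple(vs) for k, vs in new.items()})
        trees = new_trees
        next_internal += 1
    return trees


def _nj_start(presence: pd.DataFrame):
    """Neighbour-joining start topology from Hamming distances."""
    from skbio import DistanceMatrix
    from skbio.tree import nj as skbio_nj

    data = presence.to_numpy(dtype=int)
    ids = list(presence.index)
    n = len(ids)
    D = np.zeros((n, n))
    for i in range(n):
        D[i] = (data != data[i]).mean(axis=1)
    D = (D + D.T) / 2
    np.fill_diagonal(D, 0.0)
    tree = skbio_nj(DistanceMatrix(D, ids))
    # convert the (possibly rooted) skbio tree to an adjacency structure
    adj = {}
    counter = itertools.count()

    def add_edge(a, b):
        adj.setdefault(a, []).append(b)
        adj.setdefault(b, []).append(a)

    def walk(node):
        if node.is_tip():
            return node.name
        me = next(counter)
        for child in node.children:
            add_edge(me, walk(child))
        return me

    root_id = walk(tree)
    # suppress a degree-2 root by fusing its two neighbours
    if len(adj[root_id]) == 2:
        a, b = adj.pop(root_id)
        adj[a] = [b if x == root_id else x for x in adj[a]]
        adj[b] = [a if x == root_id else x for x in adj[b]]
    return {k: tuple(v) for k, v in adj.items()}


def _nni_neighbours(adj):
    """All trees one nearest-neighbour interchange away."""
    internal_edges = [
        (u, v)
        for u, nbrs in adj.items()
        for v in nbrs
        if isinstance(u, int) and isinstance(v, int) and u < v
    ]
    out = []
    for u, v in internal_edges:
        u_sub = [x for x in adj[u] if x != v]
        v_sub = [x for x in adj[v] if x != u]
        for vi in range(2):
            b, c = u_sub[1], v_sub[vi]
            new = {k: list(vs) for k, vs in adj.items()}
            new[u] = [c if x == b else x for x in new[u]]
            new[v] = [b if x == c else x for x in new[v]]
            new[b] = [v if x == u else x for x in new[b]]
            new[c] = [u if x == v else x for x in new[c]]
            out.append({k: tuple(vs) for k, vs in new.items()})
    return out


def build_tree(presence: pd.DataFrame, seed: int = 0, max_exhaustive: int = 7) -> PhyloTree:
    """Maximum-likelihood sample tree from a binary presence matrix.

    ``presence``: samples x mutations, entries 0/1. Exhaustive search over
    all unrooted topologies for <= ``max_exhaustive`` leaves, otherwise
    NNI hill climbing from a neighbour-joining start. Deterministic: ties
    between equal-likelihood topologies break on topology enumeration
    order (exhaustive) or are never taken (hill climb requires strict
    improvement).
    """
    samples = list(presence.index)
    if len(samples) < 3:
        raise ValueError("need >= 3 samples to build a tree")
    data = presence.to_numpy(dtype=int)
    if (data == data[0]).all():
        warnings.warn("all presence rows identical; returning star tree")
        adj = {0: tuple(samples)}
        for s in samples:
            adj[s] = (0,)
        return PhyloTree(adjacency=adj, leaves=tuple(samples), star=True)

    if len(samples) <= max_exhaustive:
        best, best_ll, best_t = None, -np.inf, 0.1
        for adj in _enumerate_topologies(samples):
            t, ll = _optimize_branch(adj, presence)
            if ll > best_ll + 1e-9:
                best, best_ll, best_t = adj, ll, t
        return PhyloTree(
            adjacency=best, leaves=tuple(samples),
            branch_length=best_t, log_likelihood=best_ll,
        )

    adj = _nj_start(presence)
    t, ll = _optimize_branch(adj, presence)
    improved = True
    while improved:
        improved = False
        for cand in _nni_neighbours(adj):
            tc, llc = _optimize_branch(cand, presence)
            if llc > ll + 1e-6:
                adj, t, ll = cand, tc, llc
                improved = True
                break
    return PhyloTree(adjacency=adj, leaves=tuple(samples), branch_length=t, log_likelihood=ll)


# ---------------------------------------------------------------------------
# Lineage assignment and spatial pattern

@dataclass
class LineageModel:
    """First-generation lineage labels plus the spatial pattern call."""

    labels: pd.Series  # sample_id -> L1, L2, ... or "absent"
    groups: dict  # label -> set of supporting EEM variant_ids
    inconsistent: bool
    pattern: str = "indeterminate"
    axis_scores: dict = field(default_factory=dict)
    tree: PhyloTree | None = None


def assign_lineages(
    eems: pd.DataFrame,
    sample_ids,
    tree: PhyloTree | None = None,
    containment_join: float = 0.6,
    overlap_tol: float = 0.2,
) -> LineageModel:
    """Partition samples by the earliest mutually exclusive EEM clades.

    EEMs are grouped greedily in decreasing carrier-count order: an EEM
    joins an existing group when most of its carriers (>= ``containment_join``)
    lie inside the group's founding carrier set (embryonic nesting), else
    founds a new group. Samples are labelled by majority EEM membership;
    samples carrying no grouped EEM are labelled ``absent``. Founding
    carrier sets overlapping by more than ``overlap_tol`` (Jaccard) mark
    the model inconsistent.
    """
    sample_ids = list(sample_ids)
    if len(eems) == 0:
        return LineageModel(
            labels=pd.Series("absent", index=sample_ids, dtype=object),
            groups={}, inconsistent=False,
        )
    ordered = eems.sort_values(
        ["n_carriers", "variant_id"], ascending=[False, True]
    )
    founders: list[frozenset] = []
    members: list[list] = []
    for _, row in ordered.iterrows():
        cs = row["carriers"]
        placed = False
        for gi, f in enumerate(founders):
            if len(cs & f) / len(cs) >= containment_join:
                members[gi].append(row["variant_id"])
                placed = True
                break
        if not placed:
            founders.append(frozenset(cs))
            members.append([row["variant_id"]])
    inconsistent = any(
        len(a & b) / len(a | b) > overlap_tol
        for a, b in itertools.combinations(founders, 2)
    )
    # vote: sample -> group with the most supporting EEMs carrying it
    carrier_of = dict(zip(eems["variant_id"], eems["carriers"]))
    votes = {s: np.zeros(len(founders)) for s in sample_ids}
    for gi, vids in enumerate(members):
        for vid in vids:
            for s in carrier_of[vid]:
                if s in votes:
                    votes[s][gi] += 1
    labels = {}
    for s in sample_ids:
        v = votes[s]
        labels[s] = f"L{int(np.argmax(v)) + 1}" if v.max() > 0 else "absent"
    groups = {f"L{gi+1}": set(vids) for gi, vids in enumerate(members)}
    return LineageModel(
        labels=pd.Series(labels, index=sample_ids, dtype=object),
        groups=groups, inconsistent=inconsistent, tree=tree,
    )


def _cramers_v(labels: np.ndarray, strata: np.ndarray) -> float:
    tab = pd.crosstab(pd.Series(labels), pd.Series(strata)).to_numpy()
    tab = tab[tab.sum(axis=1) > 0][:, tab.sum(axis=0) > 0]
    if tab.shape[0] < 2 or tab.shape[1] < 2:
        return 0.0
    chi2 = chi2_contingency(tab, correction=False)[0]
    n = tab.sum()
    k = min(tab.shape) - 1
    return float(np.sqrt(chi2 / (n * k))) if k > 0 else 0.0


def classify_spatial_pattern(
    labels: pd.Series,
    coords: pd.DataFrame,
    tau: float = 0.5,
    kappa: float = 0.8,
    min_samples: int = 6,
) -> tuple[str, dict]:
    """Layered / mixed / indeterminate call for first-generation lineages.

    Axis association scores are Cramér's V between lineage label and the
    stratum along each axis (vertical = layer index z, lateral = sign of x,
    antero-posterior = sign of y). *Layered*: vertical V >= tau and every
    layer's majority lineage holds >= kappa of its samples. *Mixed*: at
    least half the layers contain >= 2 lineages, the lateral score is the
    largest axis score and itself reaches tau (the magnitude requirement
    keeps weak, direction-only maxima from being called a pattern).
    """
    df = coords.loc[labels.index].copy()
    df["label"] = labels
    df = df[df["label"] != "absent"]
    lab = df["label"].to_numpy()
    scores = {"vertical": 0.0, "lateral": 0.0, "anteroposterior": 0.0}
    if len(df) < min_samples or len(set(lab)) < 2:
        return "indeterminate", scores
    lateral = df[df["x"] != 0]
    scores["vertical"] = _cramers_v(lab, df["z"].to_numpy())
    scores["lateral"] = _cramers_v(
        lateral["label"].to_numpy(), np.sign(lateral["x"].to_numpy())
    )
    ap = df[df["y"] != 0]
    scores["anteroposterior"] = _cramers_v(
        ap["label"].to_numpy(), np.sign(ap["y"].to_numpy())
    )

    layer_purity, layer_multi = [], []
    for _, grp in df.groupby("z"):
        counts = grp["label"].value_counts()
        layer_purity.append(counts.iloc[0] / counts.sum())
        layer_multi.append(len(counts) >= 2)
    layered = scores["vertical"] >= tau and all(p >= kappa for p in layer_purity)
    mixed = (
        np.mean(layer_multi) >= 0.5
        and scores["lateral"] >= max(scores.values()) - 1e-12
        and scores["lateral"] >= tau
    )
    if layered:
        return "layered", scores
    if mixed:
        return "mixed", scores
    return "indeterminate", scores


def analyze_case_lineage(
    case_variants: pd.DataFrame,
    samples: pd.DataFrame,
    build_phylogeny: bool = True,
    tau: float = 0.5,
    kappa: float = 0.8,
    seed: int = 0,
    **eem_kwargs,
) -> LineageModel:
    """EEM detection -> (optional) tree -> lineage labels -> pattern call."""
    eems = detect_eems(case_variants, **eem_kwargs)
    sids = sorted(case_variants["sample_id"].unique())
    tree = None
    if build_phylogeny and len(eems) > 0:
        presence = pd.DataFrame(
            {
                row["variant_id"]: [
                    1 if s in row["carriers"] else 0 for s in sids
                ]
                for _, row in eems.iterrows()
            },
            index=sids,
        )
        if presence.shape[1] >= 1 and len(sids) >= 3:
            tree = build_tree(presence, seed=seed)
    model = assign_lineages(eems, sids, tree=tree)
    coords = samples.set_index("sample_id").loc[sids, ["x", "y", "z"]]
    pattern, scores = classify_spatial_pattern(model.labels, coords, tau=tau, kappa=kappa)
    model.pattern = pattern
    model.axis_scores = scores
    return model
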