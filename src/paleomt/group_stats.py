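"""Haplogroup-frequency tables and frequency-based statistics.

The analysis unit is a groups × haplogroup-categories count table (default
25-category scheme).  On top of it sit: centered, unscaled PCA of relative
frequencies; Ward/Euclidean hierarchical clustering with plain bootstrap
support (categories resampled with replacement); Fisher's exact test (exact
2×2, margin-fixed Monte-Carlo for r×c); and standard HVS-I diversity indices
(haplotype diversity Hd, nucleotide diversity π, segregating sites S).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.special import gammaln

from .core_io import Dataset, GroupDefinition
from .haplogroup_typing import FALLBACK_LABEL, MotifTree

#: Default 25-category haplogroup scheme; sub-haplogroups roll up to these.
DEFAULT_SCHEME = [
    "H", "H1", "H3", "HV", "V", "J", "K", "N*", "N1a", "T", "T1", "T2",
    "U*", "U2", "U3", "U4", "U5a", "U5b", "U8", "W", "X", "R*", "L1b", "M",
    "other",
]

_STARRED = {"N": "N*", "R": "R*", "U": "U*"}


def collapse_label(label: str | None, scheme: list[str],
                   tree: MotifTree | None = None) -> str:
    """Map a haplogroup label onto its scheme category (roll-up via the tree)."""
    if label is None:
        return "other"
    if label == FALLBACK_LABEL:
        label = "H"
    tree = tree or MotifTree.default()
    cur: str | None = label
    while cur is not None:
        if cur in scheme:
            return cur
        starred = _STARRED.get(cur)
        if starred is not None and starred in scheme:
            return starred
        cur = tree.nodes[cur].parent if cur in tree.nodes else None
    return "other"


@dataclass
class HaplogroupFrequencyTable:
    """Groups × categories counts with per-group sample sizes."""

    counts: pd.DataFrame  # rows = groups, columns = categories, ints

    def __post_init__(self):
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")

    @property
    def groups(self) -> list[str]:
        return list(self.counts.index)

    @property
    def categories(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n(self) -> pd.Series:
        return self.counts.sum(axis=1)

    @property
    def frequencies(self) -> pd.DataFrame:
        return self.counts.div(self.n, axis=0)


def build_frequency_table(dataset: Dataset, groups: list[GroupDefinition],
                          scheme: list[str] | None = None,
                          tree: MotifTree | None = None) -> HaplogroupFrequencyTable:
    """Count scheme categories per group; labels outside the scheme go to ``other``."""
    scheme = scheme or DEFAULT_SCHEME
    tree = tree or MotifTree.default()
    rows = {}
    for g in groups:
        members = g.resolve(dataset)
        if not members:
            raise ValueError(f"group {g.label} has no members")
        counts = dict.fromkeys(scheme, 0)
        for ind in members:
            cat = collapse_label(ind.haplogroup, scheme, tree)
            counts[cat] = counts.get(cat, 0) + 1
        rows[g.label] = counts
    df = pd.DataFrame.from_dict(rows, orient="index")[scheme].fillna(0).astype(int)
    return HaplogroupFrequencyTable(df)


# ---------------------------------------------------------------------------
# PCA

@dataclass
class PCAResult:
    scores: pd.DataFrame       # groups × components
    loadings: pd.DataFrame     # categories × components
    variance_proportions: np.ndarray


def pca(table: HaplogroupFrequencyTable) -> PCAResult:
    """Centered, unscaled PCA of the relative-frequency rows.

    Sign convention: within each component the largest-magnitude loading is
    made positive, so results are deterministic and invariant (up to sign)
    under category reordering.
    """
    if len(table.groups) < 3:
        raise ValueError("PCA needs at least 3 groups")
    X = table.frequencies.to_numpy(dtype=float)
    Xc = X - X.mean(axis=0, keepdims=True)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    k = min(len(table.groups) - 1, len(table.categories))
    U, s, Vt = U[:, :k], s[:k], Vt[:k]
    for i in range(k):
        j = int(np.argmax(np.abs(Vt[i])))
        if Vt[i, j] < 0:
            Vt[i] *= -1
            U[:, i] *= -1
    total = float(np.sum(s ** 2))
    props = s ** 2 / total if total > 0 else np.zeros(k)
    comps = [f"PC{i + 1}" for i in range(k)]
    return PCAResult(
        scores=pd.DataFrame(U * s, index=table.groups, columns=comps),
        loadings=pd.DataFrame(Vt.T, index=table.categories, columns=comps),
        variance_proportions=props,
    )


# ---------------------------------------------------------------------------
# Ward clustering with bootstrap support

@dataclass
class ClusterTree:
    labels: list[str]
    linkage: np.ndarray                 # scipy linkage matrix
    support: dict[frozenset, float]     # internal-node leaf set -> % of bootstraps

    def newick(self) -> str:
        """Dendrogram as Newick, internal nodes labelled with bootstrap support."""
        tree = hierarchy.to_tree(self.linkage)

        def fmt(node) -> str:
            if node.is_leaf():
                return f"{self.labels[node.id]}:{node.dist:.6g}"
            left, right = fmt(node.left), fmt(node.right)
            leaves = frozenset(self.labels[i] for i in node.pre_order())
            sup = self.support.get(leaves, float("nan"))
            return f"({left},{right}){sup:.1f}:{node.dist:.6g}"

        return fmt(tree) + ";"


def _node_leaf_sets(linkage: np.ndarray, labels: list[str]) -> list[frozenset]:
    n = len(labels)
    sets: dict[int, frozenset] = {i: frozenset([labels[i]]) for i in range(n)}
    out = []
    for i, (a, b, _, _) in enumerate(linkage):
        merged = sets[int(a)] | sets[int(b)]
        sets[n + i] = merged
        out.append(merged)
    return out


def ward_cluster(table: HaplogroupFrequencyTable, n_boot: int = 1000,
                 seed: int | None = 0) -> ClusterTree:
    """Ward linkage on Euclidean distances between frequency rows.

    Support for each internal node is the plain bootstrap proportion: the
    percentage of replicate trees (categories resampled with replacement)
    whose topology contains the node's leaf set.
    """
    if len(table.groups) < 2:
        raise ValueError("clustering needs at least 2 groups")
    X = table.frequencies.to_numpy(dtype=float)
    labels = table.groups
    Z = hierarchy.linkage(X, method="ward")
    node_sets = _node_leaf_sets(Z, labels)
    hits = dict.fromkeys(node_sets, 0)
    rng = np.random.default_rng(seed)
    p = X.shape[1]
    for _ in range(n_boot):
        idx = rng.integers(0, p, size=p)
        Zb = hierarchy.linkage(X[:, idx], method="ward")
        for s in _node_leaf_sets(Zb, labels):
            if s in hits:
                hits[s] += 1
    support = {s: 100.0 * c / n_boot for s, c in hits.items()}
    return ClusterTree(labels, Z, support)


# ---------------------------------------------------------------------------
# Fisher's exact test

def _table_logprob(table: np.ndarray) -> float:
    """Log hypergeometric probability of an r×c table given its margins."""
    r, c = table.sum(axis=1), table.sum(axis=0)
    n = table.sum()
    return float(np.sum(gammaln(r + 1)) + np.sum(gammaln(c + 1))
                 - gammaln(n + 1) - np.sum(gammaln(table + 1)))


def fisher_test(counts_a, counts_b, method: str = "auto",
                n_mc: int = 100_000, seed: int | None = 0) -> float:
    """Two-sided Fisher's exact test on a 2×k category table.

    2×2 tables use the exact hypergeometric test (sum of tables at least as
    improbable as observed).  Larger tables use a margin-preserving
    Monte-Carlo test (Patefield sampling): p = (1 + #{P(sim) <= P(obs)}) /
    (n_mc + 1).  Zero-sum categories are dropped first; the statistic is
    symmetric in row and column order.
    """
    table = np.asarray([counts_a, counts_b], dtype=int)
    if table.sum() == 0:
        raise ValueError("empty table")
    table = table[:, table.sum(axis=0) > 0]
    table = table[table.sum(axis=1) > 0, :]
    if table.shape[0] < 2 or table.shape[1] < 2:
        return 1.0  # one group or one category left: margins fix the table
    if method not in {"auto", "exact", "montecarlo"}:
        raise ValueError(f"unknown method {method!r}")
    if table.shape == (2, 2) and method in {"auto", "exact"}:
        return float(stats.fisher_exact(table, alternative="two-sided")[1])
    if method == "exact":
        raise ValueError("exact enumeration only supported for 2x2 tables")
    rng = np.random.default_rng(seed)
    dist = stats.random_table(table.sum(axis=1), table.sum(axis=0))
    sims = dist.rvs(n_mc, method="patefield", random_state=rng)
    obs_lp = _table_logprob(table)
    sim_lp = (np.sum(gammaln(np.asarray(sims) + 1), axis=(1, 2)))
    # constant margin terms cancel; compare -sum(log n_ij!) to observed
    obs_core = -float(np.sum(gammaln(table + 1)))
    hits = int(np.sum(-sim_lp <= obs_core + 1e-9))
    del obs_lp
    return (1 + hits) / (n_mc + 1)


# ---------------------------------------------------------------------------
# Diversity indices

@dataclass
class DiversityIndices:
    n: int
    n_haplotypes: int
    haplotype_diversity: float
    nucleotide_diversity: float
    segregating_sites: int


def diversity(dataset: Dataset, group: GroupDefinition,
              window: tuple[int, int] | None = None) -> DiversityIndices:
    """Standard HVS-I diversity indices for one group.

    Hd is Nei's unbiased haplotype diversity n/(n-1)(1 - Σp²) over distinct
    window-clipped haplotypes; π is the mean pairwise proportion of
    differing sites (pairwise deletion of missing data); S counts positions
    with ≥2 observed bases.
    """
    window = window or dataset.window
    members = [i for i in group.resolve(dataset) if i.haplotype is not None]
    n = len(members)
    if n < 2:
        raise ValueError(f"diversity needs >= 2 sequenced individuals in {group.label}")
    keys = [tuple(sorted(i.haplotype.clipped(window).variants)) for i in members]
    counts = np.array(list(Counter(keys).values()))
    p = counts / n
    hd = n / (n - 1) * (1.0 - float(np.sum(p ** 2)))

    sub = dataset.with_individuals(members)
    seqs = list(sub.sequences(window).values())
    arr = np.frombuffer("".join(seqs).encode(), dtype="S1").reshape(n, -1)
    valid = np.isin(arr, np.array([b"A", b"C", b"G", b"T"]))
    pis = []
    for i in range(n):
        for j in range(i + 1, n):
            both = valid[i] & valid[j]
            L = int(both.sum())
            if L == 0:
                continue
            pis.append(float(np.sum(arr[i][both] != arr[j][both])) / L)
    pi = float(np.mean(pis)) if pis else 0.0

    s_count = 0
    for col in range(arr.shape[1]):
        bases = set(arr[valid[:, col], col])
        if len(bases) >= 2:
            s_count += 1
    return DiversityIndices(n, len(counts), hd, pi, s_count)
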