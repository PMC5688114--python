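"""Sequence-level statistics: TN93(+Γ) distances, ΦST, MDS and AMOVA.

Distances use the Tamura–Nei 1993 substitution model, which separates the
two transition classes (A↔G weighted by purine frequencies, C↔T by
pyrimidine frequencies) from transversions, with optional gamma-distributed
rate heterogeneity across sites (shape ``alpha``; HVS-I is strongly
rate-heterogeneous, the conventional control-region value being
alpha ≈ 0.117, with 0.177 in use for mixed ancient/modern comparisons).
Missing data are handled by pairwise deletion.

ΦST and AMOVA follow the Excoffier-style analysis of molecular variance on
squared distances; permutation p-values carry the +1 correction and the
pairwise ΦST p-values are Benjamini–Hochberg adjusted across all pairs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.manifold import MDS as _SkMDS
from statsmodels.stats.multitest import multipletests

#: Distance reported for saturated pairs (log/gamma argument <= 0).
SATURATION_DISTANCE = 10.0

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


def encode_sequence(seq: str) -> np.ndarray:
    """Encode ACGT as 0..3 and anything else (N, gaps) as -1 (missing)."""
    arr = np.full(len(seq), -1, dtype=np.int8)
    for base, code in _CODE.items():
        arr[np.frombuffer(seq.upper().encode(), dtype="S1") == base.encode()] = code
    return arr


def pooled_base_frequencies(seqs: list[str] | np.ndarray) -> np.ndarray:
    """Base frequencies (A,C,G,T) pooled over all sequences, missing excluded."""
    if isinstance(seqs, np.ndarray):
        arr = seqs
    else:
        arr = np.stack([encode_sequence(s) for s in seqs])
    counts = np.array([(arr == c).sum() for c in range(4)], dtype=float)
    if counts.sum() == 0:
        raise ValueError("no called bases to estimate frequencies from")
    return counts / counts.sum()


def tn93_gamma(seq_a: str | np.ndarray, seq_b: str | np.ndarray,
               alpha: float | None = 0.117,
               base_freqs: np.ndarray | None = None) -> tuple[float, bool]:
    """TN93 distance between two aligned sequences, optionally Γ-corrected.

    Returns ``(distance, saturated)``; saturated pairs get the flagged
    ceiling :data:`SATURATION_DISTANCE` instead of NaN.  ``alpha=None``
    disables the rate-heterogeneity correction (plain TN93 logs).  Base
    frequencies default to the two sequences pooled; for matrices they
    should be estimated once from the whole comparison (see
    :func:`tn93_matrix`).
    """
    a = encode_sequence(seq_a) if isinstance(seq_a, str) else seq_a
    b = encode_sequence(seq_b) if isinstance(seq_b, str) else seq_b
    if a.shape != b.shape:
        raise ValueError("sequences must be aligned to equal length")
    both = (a >= 0) & (b >= 0)
    L = int(both.sum())
    if L == 0:
        raise ValueError("no comparable sites (all missing)")
    if base_freqs is None:
        base_freqs = pooled_base_frequencies(np.stack([a, b]))
    pi = np.asarray(base_freqs, dtype=float)
    pi = pi / pi.sum()
    gA, gC, gG, gT = pi
    gR, gY = gA + gG, gC + gT

    av, bv = a[both], b[both]
    diff = av != bv
    is_ag = diff & (((av == 0) & (bv == 2)) | ((av == 2) & (bv == 0)))
    is_ct = diff & (((av == 1) & (bv == 3)) | ((av == 3) & (bv == 1)))
    P1 = float(is_ag.sum()) / L
    P2 = float(is_ct.sum()) / L
    Q = float((diff & ~is_ag & ~is_ct).sum()) / L

    if alpha is None or np.isinf(alpha):
        def transform(x):
            return -np.log(x)
    else:
        def transform(x):
            return alpha * (x ** (-1.0 / alpha) - 1.0)

    # Terms whose frequency coefficient vanishes (a base class absent from
    # the data) are dropped; observed changes of that class then indicate a
    # frequency/model mismatch and are flagged as saturation.
    eps = 1e-12
    k1 = 2.0 * gA * gG / gR if gR > eps else 0.0
    k2 = 2.0 * gC * gT / gY if gY > eps else 0.0
    k3 = (2.0 * (gR * gY - gA * gG * gY / gR - gC * gT * gR / gY)
          if gR > eps and gY > eps else 0.0)
    d = 0.0
    for k, Px, extra in ((k1, P1, Q / (2.0 * gR) if gR > eps else 0.0),
                         (k2, P2, Q / (2.0 * gY) if gY > eps else 0.0)):
        if k > eps:
            e = 1.0 - Px / k - extra
            if e <= 0:
                return SATURATION_DISTANCE, True
            d += k * transform(e)
        elif Px > 0:
            return SATURATION_DISTANCE, True
    if k3 > eps:
        e3 = 1.0 - Q / (2.0 * gR * gY)
        if e3 <= 0:
            return SATURATION_DISTANCE, True
        d += k3 * transform(e3)
    elif Q > 0:
        return SATURATION_DISTANCE, True
    return float(max(d, 0.0)), False


@dataclass
class PairwiseDistanceMatrix:
    ids: list[str]
    matrix: np.ndarray
    alpha: float | None
    base_freqs: np.ndarray
    saturated_pairs: list[tuple[str, str]] = field(default_factory=list)

    def submatrix(self, ids: list[str]) -> np.ndarray:
        idx = [self.ids.index(i) for i in ids]
        return self.matrix[np.ix_(idx, idx)]


def tn93_matrix(sequences: dict[str, str], alpha: float | None = 0.117,
                base_freqs: np.ndarray | None = None) -> PairwiseDistanceMatrix:
    """All-pairs TN93(+Γ) matrix; base frequencies pooled over the dataset."""
    ids = list(sequences)
    enc = [encode_sequence(sequences[i]) for i in ids]
    if base_freqs is None:
        base_freqs = pooled_base_frequencies(np.stack(enc))
    n = len(ids)
    mat = np.zeros((n, n))
    saturated = []
    for i in range(n):
        for j in range(i + 1, n):
            d, sat = tn93_gamma(enc[i], enc[j], alpha, base_freqs)
            mat[i, j] = mat[j, i] = d
            if sat:
                saturated.append((ids[i], ids[j]))
    return PairwiseDistanceMatrix(ids, mat, alpha, np.asarray(base_freqs), saturated)


# ---------------------------------------------------------------------------
# Two-level AMOVA / pairwise PhiST

def _phi_st(d2: np.ndarray, sizes: list[int]) -> float:
    """ΦST from the squared-distance variance decomposition.

    ``d2`` is the squared distance matrix with individuals ordered group by
    group; ``sizes`` the group sample sizes.  Negative estimates are
    returned raw (callers floor them for reporting).
    """
    N = sum(sizes)
    k = len(sizes)
    ssd_total = d2.sum() / (2.0 * N)  # sum over ordered pairs = 2 * sum i<j
    ssd_within = 0.0
    start = 0
    for n_g in sizes:
        block = d2[start:start + n_g, start:start + n_g]
        ssd_within += block.sum() / (2.0 * n_g)
        start += n_g
    ssd_among = ssd_total - ssd_within
    df_within = N - k
    sigma_w = ssd_within / df_within if df_within > 0 else 0.0
    n_prime = (N - sum(n ** 2 for n in sizes) / N) / (k - 1)
    ms_among = ssd_among / (k - 1)
    sigma_a = (ms_among - sigma_w) / n_prime
    denom = sigma_a + sigma_w
    return sigma_a / denom if denom != 0 else 0.0


@dataclass
class FstMatrix:
    groups: list[str]
    phi_st: pd.DataFrame        # floored at 0
    phi_st_raw: pd.DataFrame    # unfloored estimates
    p_values: pd.DataFrame
    p_adjusted: pd.DataFrame

    def slatkin(self) -> pd.DataFrame:
        """Slatkin linearization F/(1-F) of the floored values."""
        f = self.phi_st.to_numpy(dtype=float)
        with np.errstate(divide="ignore"):
            lin = np.where(f < 1.0, f / (1.0 - f), np.inf)
        return pd.DataFrame(lin, index=self.groups, columns=self.groups)


def pairwise_phist(dist: PairwiseDistanceMatrix,
                   group_members: dict[str, list[str]],
                   n_perm: int = 1000, seed: int | None = 0) -> FstMatrix:
    """Pairwise ΦST with permutation p-values and BH adjustment.

    Permutations reshuffle individuals between the two groups on the fixed
    distance matrix; p = (1 + #{Φ_perm >= Φ_obs}) / (n_perm + 1).
    """
    for lab, ids in group_members.items():
        if len(ids) < 2:
            raise ValueError(f"group {lab} has fewer than 2 individuals")
    labels = list(group_members)
    k = len(labels)
    raw = np.zeros((k, k))
    pval = np.ones((k, k))
    rng = np.random.default_rng(seed)
    pairs = list(itertools.combinations(range(k), 2))
    flat_p = []
    for i, j in pairs:
        ids = group_members[labels[i]] + group_members[labels[j]]
        sizes = [len(group_members[labels[i]]), len(group_members[labels[j]])]
        d2 = dist.submatrix(ids) ** 2
        obs = _phi_st(d2, sizes)
        raw[i, j] = raw[j, i] = obs
        n = sum(sizes)
        hits = 0
        for _ in range(n_perm):
            perm = rng.permutation(n)
            if _phi_st(d2[np.ix_(perm, perm)], sizes) >= obs - 1e-12:
                hits += 1
        p = (1 + hits) / (n_perm + 1)
        pval[i, j] = pval[j, i] = p
        flat_p.append(p)
    adj = np.ones((k, k))
    if flat_p:
        _, corrected, _, _ = multipletests(flat_p, method="fdr_bh")
        for (i, j), p_adj in zip(pairs, corrected):
            adj[i, j] = adj[j, i] = p_adj
    floored = np.clip(raw, 0.0, None)
    np.fill_diagonal(floored, 0.0)
    np.fill_diagonal(raw, 0.0)
    mk = lambda m: pd.DataFrame(m, index=labels, columns=labels)
    return FstMatrix(labels, mk(floored), mk(raw), mk(pval), mk(adj))


# ---------------------------------------------------------------------------
# Three-level AMOVA

@dataclass
class AMOVAResult:
    sigma_among_clusters: float
    sigma_among_pops: float
    sigma_within: float
    f_ct: float
    f_sc: float
    f_st: float
    p_ct: float | None = None
    p_sc: float | None = None
    p_st: float | None = None

    @property
    def total_variance(self) -> float:
        return self.sigma_among_clusters + self.sigma_among_pops + self.sigma_within


def _amova_components(d2: np.ndarray, pop_sizes: list[int],
                      clusters: list[list[int]]) -> tuple[float, float, float]:
    """Variance components (among clusters, among pops within, within pops)."""
    N = sum(pop_sizes)
    P = len(pop_sizes)
    G = len(clusters)
    starts = np.concatenate([[0], np.cumsum(pop_sizes)])
    pop_idx = [np.arange(starts[p], starts[p + 1]) for p in range(P)]
    cluster_idx = [np.concatenate([pop_idx[p] for p in g]) for g in clusters]
    cluster_sizes = [len(ix) for ix in cluster_idx]

    ssd_total = d2.sum() / (2.0 * N)
    ssd_wp = sum(d2[np.ix_(ix, ix)].sum() / (2.0 * len(ix)) for ix in pop_idx)
    ssd_wc = sum(d2[np.ix_(ix, ix)].sum() / (2.0 * len(ix)) for ix in cluster_idx)
    ssd_ap = ssd_wc - ssd_wp       # among populations within clusters
    ssd_ag = ssd_total - ssd_wc    # among clusters

    sigma_c = ssd_wp / (N - P) if N > P else 0.0

    sum_sq_by_cluster = [
        sum(pop_sizes[p] ** 2 for p in g) / cluster_sizes[gi]
        for gi, g in enumerate(clusters)
    ]
    n_coef = (N - sum(sum_sq_by_cluster)) / (P - G) if P > G else 1.0
    n_p = ((sum(sum_sq_by_cluster) - sum(s ** 2 for s in pop_sizes) / N)
           / (G - 1)) if G > 1 else 1.0
    n_pp = (N - sum(s ** 2 for s in cluster_sizes) / N) / (G - 1) if G > 1 else 1.0

    ms_ap = ssd_ap / (P - G) if P > G else 0.0
    sigma_b = (ms_ap - sigma_c) / n_coef if P > G else 0.0
    ms_ag = ssd_ag / (G - 1) if G > 1 else 0.0
    sigma_a = (ms_ag - sigma_c - n_p * sigma_b) / n_pp if G > 1 else 0.0
    return sigma_a, sigma_b, sigma_c


def amova(dist: PairwiseDistanceMatrix,
          group_members: dict[str, list[str]],
          clustering: list[list[str]],
          n_perm: int = 1000, seed: int | None = 0) -> AMOVAResult:
    """Three-level AMOVA (clusters / populations / individuals).

    ``clustering`` partitions the group labels.  Permutation schemes: Fct
    permutes whole populations among clusters; Fsc permutes individuals
    among populations within each cluster; Fst permutes individuals among
    all populations.  A single-cluster partition falls back to the
    two-level decomposition (Fct = 0).
    """
    labels = [lab for cluster in clustering for lab in cluster]
    if sorted(labels) != sorted(group_members):
        raise ValueError("clustering must partition the group labels exactly")
    ids = [i for lab in labels for i in group_members[lab]]
    pop_sizes = [len(group_members[lab]) for lab in labels]
    cluster_pops: list[list[int]] = []
    p = 0
    for cluster in clustering:
        cluster_pops.append(list(range(p, p + len(cluster))))
        p += len(cluster)
    d2 = dist.submatrix(ids) ** 2

    if len(clustering) < 2:
        sigma_a, sigma_b, sigma_c = 0.0, *_two_level(d2, pop_sizes)
    else:
        sigma_a, sigma_b, sigma_c = _amova_components(d2, pop_sizes, cluster_pops)
    total = sigma_a + sigma_b + sigma_c
    f_ct = sigma_a / total if total != 0 else 0.0
    f_sc = sigma_b / (sigma_b + sigma_c) if (sigma_b + sigma_c) != 0 else 0.0
    f_st = (sigma_a + sigma_b) / total if total != 0 else 0.0
    result = AMOVAResult(sigma_a, sigma_b, sigma_c, f_ct, f_sc, f_st)
    if n_perm <= 0:
        return result

    rng = np.random.default_rng(seed)
    N = sum(pop_sizes)
    starts = np.concatenate([[0], np.cumsum(pop_sizes)])
    hits_ct = hits_sc = hits_st = 0
    for _ in range(n_perm):
        if len(clustering) > 1:
            # Fct: permute whole populations among clusters (cluster sizes in
            # numbers of populations are preserved).
            perm_pops = rng.permutation(len(pop_sizes))
            order = np.concatenate([
                np.arange(starts[pp], starts[pp + 1]) for pp in perm_pops])
            sizes_perm = [pop_sizes[pp] for pp in perm_pops]
            a, b, c = _amova_components(d2[np.ix_(order, order)], sizes_perm,
                                        cluster_pops)
            tot = a + b + c
            if (a / tot if tot != 0 else 0.0) >= f_ct - 1e-12:
                hits_ct += 1
        # Fsc: permute individuals among populations within each cluster.
        order = np.arange(N)
        for c_pops in cluster_pops:
            ix = np.concatenate([np.arange(starts[pp], starts[pp + 1])
                                 for pp in c_pops])
            order[ix] = ix[rng.permutation(len(ix))]
        a, b, c = (_amova_components(d2[np.ix_(order, order)], pop_sizes,
                                     cluster_pops)
                   if len(clustering) > 1 else
                   (0.0, *_two_level(d2[np.ix_(order, order)], pop_sizes)))
        if (b / (b + c) if (b + c) != 0 else 0.0) >= f_sc - 1e-12:
            hits_sc += 1
        # Fst: permute individuals among all populations.
        order = rng.permutation(N)
        a, b, c = (_amova_components(d2[np.ix_(order, order)], pop_sizes,
                                     cluster_pops)
                   if len(clustering) > 1 else
                   (0.0, *_two_level(d2[np.ix_(order, order)], pop_sizes)))
        tot = a + b + c
        if ((a + b) / tot if tot != 0 else 0.0) >= f_st - 1e-12:
            hits_st += 1
    result.p_ct = (1 + hits_ct) / (n_perm + 1) if len(clustering) > 1 else None
    result.p_sc = (1 + hits_sc) / (n_perm + 1)
    result.p_st = (1 + hits_st) / (n_perm + 1)
    return result


def _two_level(d2: np.ndarray, sizes: list[int]) -> tuple[float, float]:
    """(sigma_among_pops, sigma_within) for the degenerate one-cluster case."""
    N, k = sum(sizes), len(sizes)
    ssd_total = d2.sum() / (2.0 * N)
    ssd_within = 0.0
    start = 0
    for n_g in sizes:
        ssd_within += d2[start:start + n_g, start:start + n_g].sum() / (2.0 * n_g)
        start += n_g
    sigma_w = ssd_within / (N - k) if N > k else 0.0
    n_prime = (N - sum(n ** 2 for n in sizes) / N) / (k - 1) if k > 1 else 1.0
    sigma_b = ((ssd_total - ssd_within) / (k - 1) - sigma_w) / n_prime if k > 1 else 0.0
    return sigma_b, sigma_w


# ---------------------------------------------------------------------------
# Multidimensional scaling

@dataclass
class MDSResult:
    coordinates: pd.DataFrame
    method: str
    stress: float | None = None


def mds(distances: pd.DataFrame, method: str = "classical",
        seed: int | None = 0) -> MDSResult:
    """Embed a group-level distance matrix in 2-D.

    ``classical`` is Torgerson double-centering (exact for Euclidean input);
    ``nonmetric`` is Kruskal stress-1 minimisation with monotone regression,
    deterministic under a fixed seed.  Negative input entries are floored at
    0.  An all-zero matrix yields coincident points.
    """
    labels = list(distances.index)
    D = np.clip(distances.to_numpy(dtype=float), 0.0, None)
    if len(labels) < 3:
        raise ValueError("MDS needs at least 3 groups")
    if method == "classical":
        n = len(labels)
        J = np.eye(n) - np.ones((n, n)) / n
        B = -0.5 * J @ (D ** 2) @ J
        vals, vecs = np.linalg.eigh(B)
        order = np.argsort(vals)[::-1][:2]
        vals2 = np.clip(vals[order], 0.0, None)
        coords = vecs[:, order] * np.sqrt(vals2)
        return MDSResult(pd.DataFrame(coords, index=labels, columns=["dim1", "dim2"]),
                         "classical")
    if method == "nonmetric":
        if not D.any():
            coords = np.zeros((len(labels), 2))
            return MDSResult(
                pd.DataFrame(coords, index=labels, columns=["dim1", "dim2"]),
                "nonmetric", 0.0)
        model = _SkMDS(n_components=2, metric=False, dissimilarity="precomputed",
                       random_state=seed, n_init=4, normalized_stress=True)
        coords = model.fit_transform(D)
        return MDSResult(pd.DataFrame(coords, index=labels, columns=["dim1", "dim2"]),
                         "nonmetric", float(model.stress_))
    raise ValueError(f"unknown MDS method {method!r}")


# ---------------------------------------------------------------------------

def subsample_groups(group_members: dict[str, list[str]], cap: int,
                     seed: int | None = 0) -> dict[str, list[str]]:
    """Randomly downsample each group to at most ``cap`` members (seeded)."""
    if cap < 1:
        raise ValueError("cap must be >= 1")
    rng = np.random.default_rng(seed)
    out = {}
    for lab in group_members:
        ids = group_members[lab]
        if len(ids) <= cap:
            out[lab] = list(ids)
        else:
            idx = rng.choice(len(ids), size=cap, replace=False)
            out[lab] = [ids[i] for i in sorted(idx)]
    return out
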