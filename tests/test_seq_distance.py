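"""TN93(+Γ) distances, ΦST, AMOVA and MDS against independent oracles."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.spatial import procrustes
from scipy.spatial.distance import cdist

from paleomt.seq_distance import (SATURATION_DISTANCE, PairwiseDistanceMatrix,
                                  amova, mds, pairwise_phist,
                                  pooled_base_frequencies, subsample_groups,
                                  tn93_gamma, tn93_matrix)


def tn93_oracle(P1, P2, Q, pi, alpha):
    """Independent transcription of the published TN93(+Γ) closed form."""
    gA, gC, gG, gT = pi
    gR, gY = gA + gG, gC + gT
    k1 = 2 * gA * gG / gR
    k2 = 2 * gC * gT / gY
    k3 = 2 * (gR * gY - gA * gG * gY / gR - gC * gT * gR / gY)
    e1 = 1 - P1 / k1 - Q / (2 * gR)
    e2 = 1 - P2 / k2 - Q / (2 * gY)
    e3 = 1 - Q / (2 * gR * gY)
    if alpha is None:
        f = lambda x: -math.log(x)
    else:
        f = lambda x: alpha * (x ** (-1 / alpha) - 1)
    return k1 * f(e1) + k2 * f(e2) + k3 * f(e3)


class TestTN93:
    def test_identical_sequences_zero(self):
        s = "ACGTACGTAC" * 10
        d, sat = tn93_gamma(s, s)
        assert d == 0.0 and not sat

    def test_jukes_cantor_limit(self):
        # Equal base frequencies, transitions/transversions in JC proportion
        # (each of the 6 unordered pairs equally likely), alpha -> infinity:
        # d -> -(3/4) ln(1 - (4/3) p).
        L = 6000
        p = 0.06
        n_mismatch = int(L * p)  # 360, divisible by 6
        per_pair = n_mismatch // 6
        pairs = [("A", "G"), ("C", "T"), ("A", "C"),
                 ("A", "T"), ("C", "G"), ("G", "T")]
        a = list("ACGT" * (L // 4))
        b = list(a)
        idx = 0
        for x, y in pairs:
            placed = 0
            while placed < per_pair:
                if a[idx] == x:
                    b[idx] = y
                    placed += 1
                idx += 1
        d, sat = tn93_gamma("".join(a), "".join(b), alpha=None,
                            base_freqs=np.array([0.25] * 4))
        expected = -0.75 * math.log(1 - 4 * p / 3)
        assert not sat
        assert math.isclose(d, expected, rel_tol=1e-6)

    def test_single_transition_matches_formula_oracle(self):
        # One A<->G transition among 335 comparable sites, equal frequencies,
        # alpha = 0.117.
        L = 335
        a = "ACGT" * 83 + "ACG"
        b = "G" + a[1:]
        pi = np.array([0.25] * 4)
        d, sat = tn93_gamma(a, b, alpha=0.117, base_freqs=pi)
        expected = tn93_oracle(1 / L, 0.0, 0.0, pi, 0.117)
        assert not sat
        assert math.isclose(d, expected, rel_tol=1e-12)

    def test_gamma_correction_increases_distance(self):
        a = "ACGT" * 100
        b = "G" + a[1:]
        pi = np.array([0.25] * 4)
        d_gamma, _ = tn93_gamma(a, b, alpha=0.117, base_freqs=pi)
        d_plain, _ = tn93_gamma(a, b, alpha=None, base_freqs=pi)
        assert d_gamma > d_plain

    def test_missing_data_pairwise_deletion(self):
        a = "AACGT"
        b = "GNCGT"  # site 0 differs; site 1 missing in b
        d_full, _ = tn93_gamma(a, b, alpha=None, base_freqs=np.array([0.25] * 4))
        d_ref, _ = tn93_gamma("ACGT", "GCGT", alpha=None,
                              base_freqs=np.array([0.25] * 4))
        assert math.isclose(d_full, d_ref, rel_tol=1e-12)

    def test_all_missing_rejected(self):
        with pytest.raises(ValueError, match="comparable"):
            tn93_gamma("NNN", "ACG")

    def test_saturated_pair_flagged_not_nan(self):
        a = "A" * 40 + "C" * 40
        b = "C" * 40 + "A" * 40  # 100% transversion-like divergence
        d, sat = tn93_gamma(a, b, alpha=0.117)
        assert sat and d == SATURATION_DISTANCE

    def test_pooled_frequencies(self):
        freqs = pooled_base_frequencies(["AACC", "GGTN"])
        assert np.allclose(freqs, [2 / 7, 2 / 7, 2 / 7, 1 / 7])


def two_group_ssd_oracle(d2, n1, n2):
    """Independent sum-of-squares decomposition for two groups."""
    N = n1 + n2
    ssd_total = d2.sum() / (2 * N)
    ssd_w1 = d2[:n1, :n1].sum() / (2 * n1)
    ssd_w2 = d2[n1:, n1:].sum() / (2 * n2)
    ssd_within = ssd_w1 + ssd_w2
    ssd_among = ssd_total - ssd_within
    sigma_w = ssd_within / (N - 2)
    n_prime = (N - (n1 ** 2 + n2 ** 2) / N) / 1
    sigma_a = (ssd_among / 1 - sigma_w) / n_prime
    return sigma_a / (sigma_a + sigma_w)


def dist_from_sequences(seqs: dict[str, str]):
    return tn93_matrix(seqs, alpha=None)


class TestPhiST:
    def test_identical_multisets_phi_zero_p_high(self):
        seqs = {f"a{i}": s for i, s in enumerate(["AAAA", "AAAT", "AATT"])}
        seqs.update({f"b{i}": s for i, s in enumerate(["AAAA", "AAAT", "AATT"])})
        dist = dist_from_sequences(seqs)
        members = {"A": ["a0", "a1", "a2"], "B": ["b0", "b1", "b2"]}
        res = pairwise_phist(dist, members, n_perm=200, seed=0)
        assert res.phi_st.loc["A", "B"] == 0.0
        assert res.phi_st_raw.loc["A", "B"] <= 0.0
        assert res.p_values.loc["A", "B"] > 0.5

    def test_monomorphic_distinct_groups_phi_one(self):
        seqs = {"a0": "AAAA", "a1": "AAAA", "b0": "TTTT", "b1": "TTTT"}
        dist = dist_from_sequences(seqs)
        res = pairwise_phist(dist, {"A": ["a0", "a1"], "B": ["b0", "b1"]},
                             n_perm=100, seed=0)
        assert math.isclose(res.phi_st.loc["A", "B"], 1.0, rel_tol=1e-9)

    def test_six_individual_fixture_matches_ssd_oracle(self):
        seqs = {"a0": "AAAAAA", "a1": "AAAAAT", "a2": "AAAATT",
                "b0": "TTTTAA", "b1": "TTTTAT", "b2": "TTTTTT"}
        dist = dist_from_sequences(seqs)
        members = {"A": ["a0", "a1", "a2"], "B": ["b0", "b1", "b2"]}
        res = pairwise_phist(dist, members, n_perm=0 + 50, seed=0)
        d2 = dist.submatrix(members["A"] + members["B"]) ** 2
        assert math.isclose(res.phi_st_raw.loc["A", "B"],
                            two_group_ssd_oracle(d2, 3, 3), rel_tol=1e-12)

    def test_pooled_then_split_halves_have_no_structure(self, rng):
        # Random halves of one pool: expected PhiST ~ 0.
        bases = np.array(list("ACGT"))
        pool = ["".join(bases[rng.integers(0, 4, 60)]) for _ in range(40)]
        seqs = {f"s{i}": s for i, s in enumerate(pool)}
        dist = dist_from_sequences(seqs)
        vals = []
        for trial in range(10):
            perm = rng.permutation(40)
            members = {"A": [f"s{i}" for i in perm[:20]],
                       "B": [f"s{i}" for i in perm[20:]]}
            res = pairwise_phist(dist, members, n_perm=0 + 10, seed=trial)
            vals.append(res.phi_st_raw.loc["A", "B"])
        assert abs(float(np.mean(vals))) <= 0.02

    def test_bh_adjustment_monotone_and_never_smaller(self):
        seqs = {f"g{g}i{i}": ("AAAA" if g < 2 else "TTAA") + "ACGT"
                for g in range(4) for i in range(3)}
        dist = dist_from_sequences(seqs)
        members = {f"G{g}": [f"g{g}i{i}" for i in range(3)] for g in range(4)}
        res = pairwise_phist(dist, members, n_perm=100, seed=2)
        labels = res.groups
        for i, a in enumerate(labels):
            for b in labels[i + 1:]:
                assert res.p_adjusted.loc[a, b] >= res.p_values.loc[a, b] - 1e-12

    def test_singleton_group_rejected(self):
        dist = dist_from_sequences({"a": "AAAA", "b": "AAAT", "c": "TTTT"})
        with pytest.raises(ValueError, match="fewer than 2"):
            pairwise_phist(dist, {"A": ["a", "b"], "B": ["c"]})

    def test_slatkin_linearization(self):
        mat = pd.DataFrame([[0.0, 0.2], [0.2, 0.0]], index=["A", "B"],
                           columns=["A", "B"])
        from paleomt.seq_distance import FstMatrix
        fst = FstMatrix(["A", "B"], mat, mat, mat * 0 + 1, mat * 0 + 1)
        assert math.isclose(fst.slatkin().loc["A", "B"], 0.25, rel_tol=1e-12)


def three_level_ssd_oracle(d2, pop_sizes, cluster_of_pop):
    """Independent SSD arithmetic for the 3-level decomposition."""
    N = sum(pop_sizes)
    P = len(pop_sizes)
    G = len(set(cluster_of_pop))
    starts = np.concatenate([[0], np.cumsum(pop_sizes)])
    pops = [np.arange(starts[p], starts[p + 1]) for p in range(P)]
    clusters = {}
    for p, c in enumerate(cluster_of_pop):
        clusters.setdefault(c, []).append(p)
    ssd_t = d2.sum() / (2 * N)
    ssd_wp = sum(d2[np.ix_(ix, ix)].sum() / (2 * len(ix)) for ix in pops)
    ssd_wc = 0.0
    for c_pops in clusters.values():
        ix = np.concatenate([pops[p] for p in c_pops])
        ssd_wc += d2[np.ix_(ix, ix)].sum() / (2 * len(ix))
    sigma_c = ssd_wp / (N - P)
    Ng = {c: sum(pop_sizes[p] for p in ps) for c, ps in clusters.items()}
    A = sum(sum(pop_sizes[p] ** 2 for p in ps) / Ng[c]
            for c, ps in clusters.items())
    n1 = (N - A) / (P - G)
    n2 = (A - sum(s ** 2 for s in pop_sizes) / N) / (G - 1)
    n3 = (N - sum(v ** 2 for v in Ng.values()) / N) / (G - 1)
    sigma_b = ((ssd_wc - ssd_wp) / (P - G) - sigma_c) / n1
    sigma_a = ((ssd_t - ssd_wc) / (G - 1) - sigma_c - n2 * sigma_b) / n3
    return sigma_a, sigma_b, sigma_c


class TestAmova:
    def _fixture(self, rng, distinct_clusters):
        if distinct_clusters:
            base = {"G0": "AAAAAA", "G1": "AAAAAT", "G2": "TTTTTA", "G3": "TTTTTT"}
        else:
            bases = np.array(list("ACGT"))
            base = {f"G{g}": None for g in range(4)}
        seqs = {}
        for g in range(4):
            for i in range(4):
                if distinct_clusters:
                    seqs[f"g{g}i{i}"] = base[f"G{g}"]
                else:
                    bases_arr = np.array(list("ACGT"))
                    seqs[f"g{g}i{i}"] = "".join(bases_arr[rng.integers(0, 4, 30)])
        members = {f"G{g}": [f"g{g}i{i}" for i in range(4)] for g in range(4)}
        return dist_from_sequences(seqs), members

    def test_components_match_ssd_oracle(self, rng):
        dist, members = self._fixture(rng, distinct_clusters=False)
        # Unequal sizes exercise the coefficients.
        members["G0"] = members["G0"][:3]
        members["G3"] = members["G3"][:2]
        clustering = [["G0", "G1"], ["G2", "G3"]]
        res = amova(dist, members, clustering, n_perm=0)
        ids = [i for lab in ["G0", "G1", "G2", "G3"] for i in members[lab]]
        d2 = dist.submatrix(ids) ** 2
        sizes = [len(members[f"G{g}"]) for g in range(4)]
        oa, ob, oc = three_level_ssd_oracle(d2, sizes, [0, 0, 1, 1])
        assert math.isclose(res.sigma_among_clusters, oa, rel_tol=1e-10)
        assert math.isclose(res.sigma_among_pops, ob, rel_tol=1e-10)
        assert math.isclose(res.sigma_within, oc, rel_tol=1e-10)

    def test_null_structure_fct_near_zero(self, rng):
        dist, members = self._fixture(rng, distinct_clusters=False)
        res = amova(dist, members, [["G0", "G1"], ["G2", "G3"]],
                    n_perm=200, seed=0)
        assert abs(res.f_ct) < 0.15
        assert res.p_ct > 0.05

    def test_distinct_clusters_fct_near_one(self, rng):
        dist, members = self._fixture(rng, distinct_clusters=True)
        res = amova(dist, members, [["G0", "G1"], ["G2", "G3"]],
                    n_perm=100, seed=0)
        assert res.f_ct > 0.9

    def test_f_statistics_consistent_with_components(self, rng):
        dist, members = self._fixture(rng, distinct_clusters=False)
        res = amova(dist, members, [["G0"], ["G1", "G2"], ["G3"]], n_perm=0)
        a, b, c = (res.sigma_among_clusters, res.sigma_among_pops,
                   res.sigma_within)
        assert math.isclose(res.f_ct, a / (a + b + c), rel_tol=1e-12)
        assert math.isclose(res.f_sc, b / (b + c), rel_tol=1e-12)
        assert math.isclose(res.f_st, (a + b) / (a + b + c), rel_tol=1e-12)

    def test_components_sum_near_direct_total_on_null_data(self, rng):
        # The moment estimators' sum matches the direct mean squared-distance
        # total in expectation; check within a loose band on null data.
        bases = np.array(list("ACGT"))
        seqs = {f"g{g}i{i}": "".join(bases[rng.integers(0, 4, 200)])
                for g in range(4) for i in range(8)}
        members = {f"G{g}": [f"g{g}i{i}" for i in range(8)] for g in range(4)}
        dist = dist_from_sequences(seqs)
        res = amova(dist, members, [["G0", "G1"], ["G2", "G3"]], n_perm=0)
        ids = [i for ids_ in members.values() for i in ids_]
        d2 = dist.submatrix(ids) ** 2
        N = len(ids)
        total_direct = d2.sum() / (2 * N) / (N - 1)
        assert abs(res.total_variance - total_direct) / total_direct < 0.1

    def test_single_cluster_falls_back_to_two_level(self, rng):
        dist, members = self._fixture(rng, distinct_clusters=False)
        res = amova(dist, members, [["G0", "G1", "G2", "G3"]], n_perm=50, seed=0)
        assert res.sigma_among_clusters == 0.0 and res.p_ct is None

    def test_bad_partition_rejected(self, rng):
        dist, members = self._fixture(rng, distinct_clusters=False)
        with pytest.raises(ValueError, match="partition"):
            amova(dist, members, [["G0"], ["G1"]], n_perm=0)


class TestMDS:
    def test_classical_recovers_planar_configuration(self, rng):
        pts = rng.random((4, 2)) * 10
        D = cdist(pts, pts)
        res = mds(pd.DataFrame(D, index=list("abcd"), columns=list("abcd")))
        _, _, disparity = procrustes(pts, res.coordinates.to_numpy())
        assert disparity < 1e-8

    def test_all_zero_matrix_coincident_points(self):
        D = pd.DataFrame(np.zeros((3, 3)), index=list("abc"), columns=list("abc"))
        res = mds(D)
        assert np.allclose(res.coordinates.to_numpy(), 0.0)

    def test_nonmetric_deterministic_and_fits_distorted_input(self, rng):
        pts = rng.random((6, 2)) * 5
        D = np.sqrt(cdist(pts, pts))  # monotone distortion of Euclidean input
        df = pd.DataFrame(D, index=list("abcdef"), columns=list("abcdef"))
        res1 = mds(df, method="nonmetric", seed=42)
        res2 = mds(df, method="nonmetric", seed=42)
        assert np.allclose(res1.coordinates, res2.coordinates)
        assert res1.stress is not None and res1.stress < 0.1

    def test_unknown_method_rejected(self):
        D = pd.DataFrame(np.zeros((3, 3)), index=list("abc"), columns=list("abc"))
        with pytest.raises(ValueError, match="method"):
            mds(D, method="sammon")


class TestSubsample:
    def test_cap_applied_only_when_exceeded(self):
        groups = {"big": [f"b{i}" for i in range(200)],
                  "small": [f"s{i}" for i in range(50)]}
        out = subsample_groups(groups, cap=140, seed=0)
        assert len(out["big"]) == 140 and len(out["small"]) == 50
        assert set(out["big"]) <= set(groups["big"])

    def test_deterministic_under_seed(self):
        groups = {"big": [f"b{i}" for i in range(200)]}
        assert subsample_groups(groups, 140, seed=9) == subsample_groups(
            groups, 140, seed=9)

    def test_invalid_cap_rejected(self):
        with pytest.raises(ValueError, match="cap"):
            subsample_groups({"a": ["x"]}, cap=0)
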