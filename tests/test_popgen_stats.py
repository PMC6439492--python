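"""Diversity and differentiation statistics against brute-force oracles."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from kelpabc.datasets import (
    MsatGenotypeMatrix,
    PopulationPartition,
    SequenceAlignment,
)
from kelpabc import popgen_stats as pg

from _oracles import (
    amova_direct,
    fst_haplotype_hand,
    hd_pair_enumeration,
    pi_pair_enumeration,
    pic_double_loop,
    richness_exact,
    richness_monte_carlo,
    segregating_sites_direct,
    wc_theta_direct,
)


# ---------------------------------------------------------------------------
# sequence diversity
# ---------------------------------------------------------------------------


class TestSeqDiversity:
    def test_no_variation(self):
        aln = SequenceAlignment(["ACGT"] * 4)
        s = pg.seq_diversity(aln)
        assert (s.S, s.h, s.Hd, s.Pi) == (0, 1, 0.0, 0.0)

    def test_three_haplotypes_of_four(self):
        # haplotype counts (2,1,1): 1 identical pair of 6 -> Hd = 5/6
        aln = SequenceAlignment(["AAAA", "AAAA", "AAAT", "AATT"])
        s = pg.seq_diversity(aln)
        assert s.h == 3
        assert s.Hd == pytest.approx(5.0 / 6.0, abs=1e-12)
        assert round(s.Hd, 4) == 0.8333

    def test_single_pair_one_mismatch(self):
        aln = SequenceAlignment(["ACGTACGTAC", "ACGTACGTAA"])
        s = pg.seq_diversity(aln)
        assert s.S == 1
        assert s.Pi == pytest.approx(0.1, abs=1e-12)

    def test_single_sequence_flagged_undefined(self):
        s = pg.seq_diversity(SequenceAlignment(["ACGT"]))
        assert (s.S, s.h) == (0, 1)
        assert np.isnan(s.Hd) and np.isnan(s.Pi)

    def test_gap_and_n_sites_excluded(self):
        aln = SequenceAlignment(["ANGT", "A-GT", "ACGA"])
        # column 2 has only one observed base ('C'); column 4 segregates
        assert pg.seq_diversity(aln).S == 1

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_matches_pair_enumeration(self, seed):
        """Hd/Pi/S agree exactly with explicit pair enumeration (n <= 30)."""
        r = np.random.default_rng(seed)
        n = int(r.integers(2, 30))
        L = int(r.integers(4, 25))
        base = r.integers(0, 4, size=L)
        seqs = []
        for _ in range(n):
            s = base.copy()
            nmut = int(r.integers(0, 4))
            s[r.integers(0, L, size=nmut)] = r.integers(0, 4, size=nmut)
            seqs.append("".join("ACGT"[int(b)] for b in s))
        aln = SequenceAlignment(seqs)
        got = pg.seq_diversity(aln)
        assert got.Hd == pytest.approx(hd_pair_enumeration(seqs), abs=1e-9)
        assert got.Pi == pytest.approx(pi_pair_enumeration(seqs), abs=1e-9)
        assert got.S == segregating_sites_direct(seqs)


def test_top_haplotype_percentage():
    assert pg.top_haplotype_percentage([3, 2, 1]) == pytest.approx(50.0)
    with pytest.raises(ValueError):
        pg.top_haplotype_percentage([])


# ---------------------------------------------------------------------------
# microsatellite diversity
# ---------------------------------------------------------------------------


def _geno_from_pairs(pairs_per_ind, ids=None):
    arr = np.array(pairs_per_ind, dtype=np.int64)[:, None, :]
    ids = ids or [f"i{k}" for k in range(arr.shape[0])]
    return MsatGenotypeMatrix(arr, ids)


def _single_pop(n):
    return PopulationPartition({f"i{k}": "pop" for k in range(n)})


class TestMsatDiversity:
    def test_monomorphic_locus(self):
        geno = _geno_from_pairs([(7, 7)] * 6)
        out = pg.msat_diversity(geno, _single_pop(6), g=3)
        row = out.loc["pop"]
        assert row["H_E"] == 0.0
        assert row["A_R"] == pytest.approx(1.0)
        assert row["PIC"] == 0.0
        assert row["H_O"] == 0.0

    def test_balanced_biallelic(self):
        # all heterozygotes: p = (0.5, 0.5) -> H_E = 0.5, PIC = 0.375
        geno = _geno_from_pairs([(10, 12)] * 8)
        row = pg.msat_diversity(geno, _single_pop(8), g=2).loc["pop"]
        assert row["H_E"] == pytest.approx(0.5)
        assert row["PIC"] == pytest.approx(0.375)
        assert row["H_O"] == 1.0

    def test_richness_rare_allele_example(self):
        # 24 gene copies, counts (23, 1), rarefied to 12 genes -> 1.5
        pairs = [(5, 5)] * 11 + [(5, 9)]
        geno = _geno_from_pairs(pairs)
        row = pg.msat_diversity(geno, _single_pop(12), g=6).loc["pop"]
        assert row["A_R"] == pytest.approx(1.5, abs=1e-12)
        assert row["A_R"] == pytest.approx(richness_exact([23, 1], 12), abs=1e-12)

    def test_richness_matches_monte_carlo(self, rng):
        counts = [11, 6, 4, 3]
        exact = richness_exact(counts, 10)
        mc = richness_monte_carlo(counts, 10, rng, reps=20000)
        assert exact == pytest.approx(mc, abs=0.03)

    @pytest.mark.parametrize("counts", [[23, 1], [10, 8, 6], [5, 5, 5, 5, 4]])
    def test_richness_monotone_in_g(self, counts):
        total = sum(counts)
        vals = [
            pg._rarefied_richness(np.array(counts), g2)
            for g2 in range(2, total + 1, 2)
        ]
        assert all(b >= a - 1e-12 for a, b in zip(vals, vals[1:]))
        # at the full sample the rarefied count equals the observed count
        assert pg._rarefied_richness(np.array(counts), total) == pytest.approx(
            len(counts)
        )

    def test_pic_matches_double_loop(self, rng):
        counts = rng.integers(1, 20, size=6)
        p = counts / counts.sum()
        pairs = []
        copies = np.repeat(np.arange(6) + 10, counts)
        rng.shuffle(copies)
        if copies.size % 2:
            copies = copies[:-1]
        pairs = list(zip(copies[::2], copies[1::2]))
        geno = _geno_from_pairs(pairs)
        row = pg.msat_diversity(geno, _single_pop(len(pairs)), g=1).loc["pop"]
        # frequencies from the data, oracle from the explicit double loop
        vals, cnt = np.unique(copies, return_counts=True)
        assert row["PIC"] == pytest.approx(
            pic_double_loop(list(cnt / cnt.sum())), abs=1e-12
        )

    def test_private_alleles_and_missing(self):
        arr = np.array(
            [
                [[10, 10]],
                [[10, 11]],
                [[-1, -1]],
                [[12, 12]],
                [[10, 10]],
                [[10, 10]],
            ],
            dtype=np.int64,
        )
        geno = MsatGenotypeMatrix(arr, [f"i{k}" for k in range(6)])
        part = PopulationPartition(
            {"i0": "A", "i1": "A", "i2": "A", "i3": "B", "i4": "B", "i5": "B"}
        )
        out = pg.msat_diversity(geno, part, g=1)
        assert out.loc["A", "N_P"] == 1.0  # allele 11 private to A
        assert out.loc["B", "N_P"] == 1.0  # allele 12 private to B
        assert out.loc["A", "n"] == 3

    def test_empty_population_errors(self):
        geno = _geno_from_pairs([(10, 10)] * 2)
        part = PopulationPartition({"i0": "A", "i1": "A", "ghost": "B"})
        with pytest.raises(ValueError):
            pg.msat_diversity(geno, part, g=1)


# ---------------------------------------------------------------------------
# Weir-Cockerham theta
# ---------------------------------------------------------------------------


def _two_pop_partition(n1, n2):
    d = {f"i{k}": "A" for k in range(n1)}
    d.update({f"i{k + n1}": "B" for k in range(n2)})
    return PopulationPartition(d)


class TestWeirCockerham:
    def test_identical_allele_counts_near_zero(self, rng):
        # one balanced biallelic locus, identical composition in both pops
        half = [(10, 12)] * 25 + [(10, 10)] * 13 + [(12, 12)] * 12
        geno = _geno_from_pairs(half + half)
        theta = pg.pairwise_fst_msat(geno, _two_pop_partition(50, 50)).loc["A", "B"]
        assert abs(theta) < 0.02

    def test_fixed_differences_give_one(self):
        geno = _geno_from_pairs([(10, 10)] * 10 + [(14, 14)] * 10)
        theta = pg.pairwise_fst_msat(geno, _two_pop_partition(10, 10)).loc["A", "B"]
        assert theta == pytest.approx(1.0)

    def test_matches_direct_component_algebra(self, rng):
        n1, n2, n_loci = 10, 10, 3
        arr = rng.integers(10, 15, size=(n1 + n2, n_loci, 2))
        geno = MsatGenotypeMatrix(arr, [f"i{k}" for k in range(n1 + n2)])
        part = _two_pop_partition(n1, n2)
        theta = pg.pairwise_fst_msat(geno, part).loc["A", "B"]
        pop1 = [
            [tuple(arr[i, l]) for i in range(n1)] for l in range(n_loci)
        ]
        pop2 = [
            [tuple(arr[i + n1, l]) for i in range(n2)] for l in range(n_loci)
        ]
        assert theta == pytest.approx(wc_theta_direct(pop1, pop2), abs=1e-9)

    @settings(derandomize=True, max_examples=15, deadline=None)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_invariant_under_relabeling(self, seed):
        """Theta is unchanged by allele relabeling and population swap."""
        r = np.random.default_rng(seed)
        arr = r.integers(10, 16, size=(16, 2, 2))
        geno = MsatGenotypeMatrix(arr, [f"i{k}" for k in range(16)])
        part = _two_pop_partition(8, 8)
        t1 = pg.pairwise_fst_msat(geno, part).loc["A", "B"]
        # bijective allele relabeling
        perm = {v: 100 + i for i, v in enumerate(np.unique(arr))}
        relabeled = np.vectorize(perm.get)(arr).astype(np.int64)
        t2 = pg.pairwise_fst_msat(
            MsatGenotypeMatrix(relabeled, [f"i{k}" for k in range(16)]), part
        ).loc["A", "B"]
        # population swap
        swapped = PopulationPartition(
            {
                k: ("B" if v == "A" else "A")
                for k, v in part.individual_to_population.items()
            }
        )
        t3 = pg.pairwise_fst_msat(geno, swapped).loc["A", "B"]
        if np.isnan(t1):
            assert np.isnan(t2) and np.isnan(t3)
        else:
            assert t1 == pytest.approx(t2, abs=1e-12)
            assert t1 == pytest.approx(t3, abs=1e-12)

    def test_clamp_negative_flag(self, rng):
        half = [(10, 12)] * 10
        geno = _geno_from_pairs(half + half)
        part = _two_pop_partition(10, 10)
        raw = pg.pairwise_fst_msat(geno, part).loc["A", "B"]
        clamped = pg.pairwise_fst_msat(geno, part, clamp_negative=True).loc["A", "B"]
        assert clamped == max(raw, 0.0)

    def test_tiny_population_errors(self):
        geno = _geno_from_pairs([(10, 11)] * 3)
        part = PopulationPartition({"i0": "A", "i1": "A", "i2": "B"})
        with pytest.raises(ValueError):
            pg.pairwise_fst_msat(geno, part)


# ---------------------------------------------------------------------------
# haplotype-frequency F_ST
# ---------------------------------------------------------------------------


class TestSequenceFst:
    def _make(self, seqs1, seqs2):
        ids = [f"i{k}" for k in range(len(seqs1) + len(seqs2))]
        aln = SequenceAlignment(seqs1 + seqs2, ids)
        part = PopulationPartition(
            {ids[k]: ("A" if k < len(seqs1) else "B") for k in range(len(ids))}
        )
        return aln, part

    def test_identical_distributions_near_zero(self):
        # the unbiased estimator is mildly negative for identical samples;
        # it approaches 0 as n grows
        seqs = ["AAAA", "AAAT"] * 15
        aln, part = self._make(seqs, seqs)
        assert abs(pg.pairwise_fst_sequences(aln, part).loc["A", "B"]) < 0.05

    def test_fixed_differences_give_one(self):
        aln, part = self._make(["AAAA"] * 4, ["TTTT"] * 4)
        assert pg.pairwise_fst_sequences(aln, part).loc["A", "B"] == pytest.approx(1.0)

    def test_monomorphic_pair_defined_zero(self):
        aln, part = self._make(["AAAA"] * 3, ["AAAA"] * 3)
        assert pg.pairwise_fst_sequences(aln, part).loc["A", "B"] == 0.0

    def test_matches_hand_algebra(self):
        # haplotype counts (3,1) vs (1,3)
        aln, part = self._make(
            ["AAAA", "AAAA", "AAAA", "TTTT"], ["AAAA", "TTTT", "TTTT", "TTTT"]
        )
        got = pg.pairwise_fst_sequences(aln, part).loc["A", "B"]
        assert got == pytest.approx(fst_haplotype_hand([3, 1], [1, 3]), abs=1e-12)


# ---------------------------------------------------------------------------
# (delta-mu)^2 and classification index
# ---------------------------------------------------------------------------


class TestDeltaMuSq:
    def test_equal_means_zero(self):
        geno = _geno_from_pairs([(10, 14)] * 4 + [(12, 12)] * 4)
        assert pg.pairwise_delta_mu_sq(geno, _two_pop_partition(4, 4)).loc[
            "A", "B"
        ] == pytest.approx(0.0)

    def test_mean_difference_squared(self):
        geno = _geno_from_pairs([(10, 10)] * 4 + [(13, 13)] * 4)
        assert pg.pairwise_delta_mu_sq(geno, _two_pop_partition(4, 4)).loc[
            "A", "B"
        ] == pytest.approx(9.0)

    def test_locus_average(self):
        arr = np.array(
            [[[10, 10], [20, 20]]] * 3 + [[[12, 12], [24, 24]]] * 3, dtype=np.int64
        )
        geno = MsatGenotypeMatrix(arr, [f"i{k}" for k in range(6)])
        # per-locus values 4 and 16 -> mean 10
        assert pg.pairwise_delta_mu_sq(geno, _two_pop_partition(3, 3)).loc[
            "A", "B"
        ] == pytest.approx(10.0)


class TestClassificationIndex:
    def test_certain_assignment_is_zero(self):
        geno = _geno_from_pairs([(10, 10)] * 3 + [(10, 10)] * 3)
        part = _two_pop_partition(3, 3)
        assert pg.classification_index(
            geno, part, "A", "B", pseudocount=False
        ) == pytest.approx(0.0)

    def test_balanced_heterozygote(self):
        # target freqs (0.5, 0.5); heterozygote prob 2pq = 0.5
        geno = _geno_from_pairs([(10, 12)] * 3 + [(10, 10), (12, 12), (10, 12), (12, 10)])
        d = {f"i{k}": "A" for k in range(3)}
        d.update({f"i{k + 3}": "B" for k in range(4)})
        part = PopulationPartition(d)
        got = pg.classification_index(geno, part, "A", "B", pseudocount=False)
        assert got == pytest.approx(np.log10(0.5), abs=1e-12)

    def test_self_symmetry_for_identical_pops(self, rng):
        pairs = [tuple(p) for p in rng.integers(10, 14, size=(12, 2))]
        geno = _geno_from_pairs(pairs + pairs)
        part = _two_pop_partition(12, 12)
        cross = pg.classification_index(geno, part, "A", "B")
        self_ = pg.classification_index(geno, part, "A", "A")
        assert cross == pytest.approx(self_, abs=0.5)

    def test_unseen_allele_without_pseudocount_errors(self):
        geno = _geno_from_pairs([(10, 10), (11, 11), (12, 12), (12, 12)])
        part = _two_pop_partition(2, 2)
        with pytest.raises(ValueError):
            pg.classification_index(geno, part, "A", "B", pseudocount=False)


# ---------------------------------------------------------------------------
# single-pass bundles agree with the reference functions
# ---------------------------------------------------------------------------


class TestGroupBundles:
    @settings(derandomize=True, max_examples=10, deadline=None)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_msat_bundle_matches_reference_functions(self, seed):
        r = np.random.default_rng(seed)
        n = 18
        arr = r.integers(10, 16, size=(n, 3, 2))
        miss = r.random((n, 3)) < 0.1
        arr[miss] = -1
        # avoid all-missing loci in a population for the reference path
        arr[0], arr[6], arr[12] = arr[0], arr[6], arr[12]
        geno = MsatGenotypeMatrix(arr, [f"i{k}" for k in range(n)])
        part = PopulationPartition(
            {f"i{k}": "ABC"[k // 6] for k in range(n)}
        )
        bundle = pg.msat_group_bundle(geno, part)
        ref_basics = pg.msat_basic_summaries(geno, part)
        for col in ("N_A", "H_E", "V"):
            np.testing.assert_allclose(
                bundle["basics"][col].sort_index(),
                ref_basics[col].sort_index(),
                atol=1e-12,
            )
        ref_fst = pg.pairwise_fst_msat(geno, part)
        ref_dmu = pg.pairwise_delta_mu_sq(geno, part)
        for g1, g2 in itertools.combinations("ABC", 2):
            got = bundle["fst"].loc[g1, g2]
            want = ref_fst.loc[g1, g2]
            assert (np.isnan(got) and np.isnan(want)) or got == pytest.approx(
                want, abs=1e-12
            )
            assert bundle["dmu2"].loc[g1, g2] == pytest.approx(
                ref_dmu.loc[g1, g2], abs=1e-12
            )
            want_lik = 0.5 * (
                pg.classification_index(geno, part, g1, g2)
                + pg.classification_index(geno, part, g2, g1)
            )
            assert bundle["lik"].loc[g1, g2] == pytest.approx(want_lik, abs=1e-12)

    def test_sequence_bundle_matches_reference_functions(self, rng):
        n = 15
        base = rng.integers(0, 4, size=30)
        seqs = []
        for _ in range(n):
            s = base.copy()
            k = int(rng.integers(0, 4))
            s[rng.integers(0, 30, size=k)] = rng.integers(0, 4, size=k)
            seqs.append("".join("ACGT"[int(b)] for b in s))
        aln = SequenceAlignment(seqs, [f"i{k}" for k in range(n)])
        part = PopulationPartition({f"i{k}": "ABC"[k // 5] for k in range(n)})
        bundle = pg.sequence_group_bundle(aln, part)
        ref = pg.sequence_group_summaries(aln, part)
        for col in ("h", "S", "MPD"):
            np.testing.assert_allclose(
                bundle["summaries"][col].sort_index(), ref[col].sort_index(),
                atol=1e-12,
            )
        ref_fst = pg.pairwise_fst_sequences(aln, part)
        ids = {g: [f"i{k}" for k in range(n) if "ABC"[k // 5] == g] for g in "ABC"}
        for g1, g2 in itertools.combinations("ABC", 2):
            assert bundle["fst"].loc[g1, g2] == pytest.approx(
                ref_fst.loc[g1, g2], abs=1e-12
            )
            sub1 = aln.subset(aln.index_of(ids[g1]))
            sub2 = aln.subset(aln.index_of(ids[g2]))
            assert bundle["mpd_between"].loc[g1, g2] == pytest.approx(
                pg.mean_between_differences(sub1, sub2), abs=1e-12
            )


# ---------------------------------------------------------------------------
# AMOVA
# ---------------------------------------------------------------------------


def _amova_fixture():
    """3 populations x 4 sequences in 2 groups, fixed composition."""
    seqs = (
        ["AAAA"] * 3 + ["AAAT"]          # pop1 (group X)
        + ["AATT"] * 2 + ["AAAT"] * 2    # pop2 (group X)
        + ["TTTT"] * 3 + ["TTTA"]        # pop3 (group Y)
    )
    ids = [f"i{k}" for k in range(12)]
    aln = SequenceAlignment(seqs, ids)
    pops = ["p1"] * 4 + ["p2"] * 4 + ["p3"] * 4
    groups = {"p1": "X", "p2": "X", "p3": "Y"}
    part = PopulationPartition(dict(zip(ids, pops)), groups)
    return aln, part, pops, [groups[p] for p in pops]


class TestAmova:
    def test_all_identical_percentages_convention(self):
        aln = SequenceAlignment(["ACGT"] * 8, [f"i{k}" for k in range(8)])
        part = PopulationPartition(
            {f"i{k}": f"p{k // 2}" for k in range(8)},
            {"p0": "X", "p1": "X", "p2": "Y", "p3": "Y"},
        )
        res = pg.amova_sequences(aln, part)
        assert res.percent == (0.0, 0.0, 100.0)
        assert res.sigma == (0.0, 0.0, 0.0)

    def test_two_fixed_groups_all_variance_among_groups(self):
        aln = SequenceAlignment(
            ["AAAA"] * 6 + ["TTTT"] * 6, [f"i{k}" for k in range(12)]
        )
        part = PopulationPartition(
            {f"i{k}": f"p{k // 3}" for k in range(12)},
            {"p0": "X", "p1": "X", "p2": "Y", "p3": "Y"},
        )
        res = pg.amova_sequences(aln, part)
        assert res.percent[0] == pytest.approx(100.0, abs=1e-6)
        assert res.phi_ct == pytest.approx(1.0, abs=1e-9)

    def test_matches_brute_force_partition(self):
        aln, part, pops, groups = _amova_fixture()
        res = pg.amova_sequences(aln, part)
        d2 = pg._sequence_sq_distance_matrix(aln)
        sig = amova_direct(d2, pops, groups)
        assert res.sigma == pytest.approx(sig, abs=1e-9)
        assert sum(res.percent) == pytest.approx(100.0, abs=1e-6)

    def test_permuting_within_populations_invariant(self, rng):
        aln, part, pops, groups = _amova_fixture()
        res1 = pg.amova_sequences(aln, part)
        # shuffle individuals within pop1 (rows 0..3)
        order = np.concatenate([rng.permutation(4), np.arange(4, 12)])
        aln2 = aln.subset(order)
        res2 = pg.amova_sequences(aln2, part)
        assert res1.sigma == pytest.approx(res2.sigma, abs=1e-9)

    def test_two_level_fallback_without_groups(self):
        aln, _, pops, _ = _amova_fixture()
        part = PopulationPartition(dict(zip(aln.ids, pops)))
        res = pg.amova_sequences(aln, part)
        assert res.sigma[0] == 0.0
        assert np.isnan(res.phi_ct)
        assert sum(res.percent) == pytest.approx(100.0, abs=1e-6)

    def test_msat_amova_runs_and_sums(self, rng):
        arr = rng.integers(10, 13, size=(12, 3, 2))
        geno = MsatGenotypeMatrix(arr, [f"i{k}" for k in range(12)])
        pops = ["p1"] * 4 + ["p2"] * 4 + ["p3"] * 4
        part = PopulationPartition(
            dict(zip(geno.individual_ids, pops)), {"p1": "X", "p2": "X", "p3": "Y"}
        )
        res = pg.amova_msat(geno, part)
        assert sum(res.percent) == pytest.approx(100.0, abs=1e-6)
        d2 = pg._msat_sq_distance_matrix(geno)
        sig = amova_direct(d2, pops, ["X", "X", "X", "X", "X", "X", "X", "X", "Y", "Y", "Y", "Y"])
        assert res.sigma == pytest.approx(sig, abs=1e-9)
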