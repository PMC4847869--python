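import numpy as np
import pytest

from indelsweep.alignment import HaplotypeAlignment
from indelsweep.popstats import (
    TajimaConstants,
    WindowSpec,
    hudson_fst,
    pairwise_pi,
    segregating_sites,
    sliding_windows,
    summary_stats,
    tajima_d,
    tajima_d_pvalue,
    watterson_theta,
)
from indelsweep.coalescent import (
    drop_mutations_fixed_s,
    drop_mutations_theta,
    simulate_genealogy,
    simulate_replicates,
)
from indelsweep.popstats import _pi_from_matrix
from indelsweep.synth import SynthSpec, make_alignment


class TestSegregatingSites:
    def test_toy_hand_count(self, toy_alignment):
        S, L_eff = segregating_sites(toy_alignment)
        assert (S, L_eff) == (3, 3)

    def test_identical_sequences(self):
        aln = HaplotypeAlignment(ids=list("ab"), seqs=["ACGT", "ACGT"])
        assert segregating_sites(aln)[0] == 0

    def test_requires_two_sequences(self):
        aln = HaplotypeAlignment(ids=["a"], seqs=["ACGT"])
        with pytest.raises(ValueError):
            segregating_sites(aln)

    def test_gapped_column_not_counted(self):
        aln = HaplotypeAlignment(ids=list("abc"), seqs=["AC", "A-", "AT"])
        S, L_eff = segregating_sites(aln)
        assert (S, L_eff) == (0, 1)


class TestWattersonTheta:
    @pytest.mark.parametrize(
        "S,n,L,expected",
        [
            (3, 2, 100, 3.0),          # a1 = 1 for n = 2
            (0, 5, 100, 0.0),
            (3, 4, 3, 600 / 11),       # a1 = 11/6
        ],
    )
    def test_hand_values(self, S, n, L, expected):
        assert watterson_theta(S, n, L) == pytest.approx(expected, rel=1e-12)

    def test_zero_length_errors(self):
        with pytest.raises(ValueError):
            watterson_theta(1, 4, 0)


class TestPi:
    def test_toy_hand_value(self, toy_alignment):
        # 10 total differences over 6 pairs and 3 sites
        assert pairwise_pi(toy_alignment) == pytest.approx(100 * (10 / 6) / 3)

    def test_identical_zero(self):
        aln = HaplotypeAlignment(ids=list("ab"), seqs=["ACGT", "ACGT"])
        assert pairwise_pi(aln) == 0.0

    def test_one_in_hundred(self):
        s = "A" * 100
        aln = HaplotypeAlignment(ids=list("ab"), seqs=[s, "T" + s[1:]])
        assert pairwise_pi(aln) == pytest.approx(1.0)


class TestTajimaD:
    def test_constants_a1(self):
        c = TajimaConstants.from_n(12)
        assert c.a1 == pytest.approx(sum(1 / i for i in range(1, 12)))

    def test_toy_value(self):
        # S=3, n=4, pi_locus = 10/6; hand-evaluated constants
        assert tajima_d(3, 4, 10 / 6) == pytest.approx(0.17, abs=0.005)

    def test_zero_numerator(self):
        a1 = TajimaConstants.from_n(6).a1
        assert tajima_d(5, 6, 5 / a1) == pytest.approx(0.0, abs=1e-12)

    def test_no_segregating_sites_undefined(self):
        assert tajima_d(0, 10, 0.0) is None

    def test_null_distribution_centered(self):
        rng = np.random.default_rng(1)
        ds = []
        for _ in range(2000):
            g = simulate_genealogy(10, rng=rng)
            rep = drop_mutations_theta(g, 5.0, rng=rng)
            if rep.segsites:
                d = tajima_d(rep.segsites, 10, _pi_from_matrix(rep.haplotypes))
                ds.append(d)
        assert abs(np.mean(ds)) < 0.2

    def test_extreme_negative_d_is_significant(self):
        p = tajima_d_pvalue(-5.0, n=12, S=41, reps=2000, seed=2)
        assert p < 0.01

    def test_pvalue_self_consistency_at_null_quantile(self):
        # D at its own null 95% |D| quantile should earn p close to 0.05
        rng = np.random.default_rng(3)
        ds = []
        for _ in range(3000):
            g = simulate_genealogy(10, rng=rng)
            rep = drop_mutations_fixed_s(g, 12, rng=rng)
            ds.append(tajima_d(12, 10, _pi_from_matrix(rep.haplotypes)))
        d_crit = np.quantile(np.abs(ds), 0.95)
        p = tajima_d_pvalue(d_crit, n=10, S=12, reps=3000, seed=4)
        assert p == pytest.approx(0.05, abs=0.015)


class TestFst:
    def test_fixed_difference_is_one(self):
        aln = HaplotypeAlignment(
            ids=list("abcd"), seqs=["AA", "AA", "TT", "TT"], pop=["x", "x", "y", "y"]
        )
        assert hudson_fst(aln, "x", "y").fst == pytest.approx(1.0)

    def test_hand_enumeration_single_site(self):
        aln = HaplotypeAlignment(
            ids=list("abcd"), seqs=["A", "T", "T", "T"], pop=["x", "x", "y", "y"]
        )
        res = hudson_fst(aln, "x", "y")
        assert res.hw == pytest.approx(0.5)
        assert res.hb == pytest.approx(0.5)
        assert res.fst == pytest.approx(0.0)

    def test_random_split_near_zero(self):
        aln, _ = make_alignment(
            SynthSpec(scenario="neutral-constant", n=16, theta=8.0, locus_length=800, seed=21)
        )
        rng = np.random.default_rng(0)
        labels = np.array(["x"] * 8 + ["y"] * 8)
        rng.shuffle(labels)
        aln.pop = list(labels)
        res = hudson_fst(aln, "x", "y")
        assert abs(res.fst) < 0.25

    def test_identical_populations_zero_hb_missing(self):
        aln = HaplotypeAlignment(
            ids=list("abcd"), seqs=["AC", "AC", "AC", "AC"], pop=["x", "x", "y", "y"]
        )
        assert hudson_fst(aln, "x", "y").fst is None


class TestSlidingWindows:
    def test_grid_arithmetic_6000_columns(self):
        aln, _ = make_alignment(
            SynthSpec(scenario="neutral-constant", n=4, theta=3.0, locus_length=6000, seed=5)
        )
        df = sliding_windows(aln, WindowSpec(500, 250))
        assert len(df) == 23
        assert df["start"].iloc[0] == 1
        assert df["start"].iloc[-1] == 5501

    def test_identical_sequences_zero_theta(self):
        aln = HaplotypeAlignment(ids=list("ab"), seqs=["ACGT" * 300] * 2)
        df = sliding_windows(aln, WindowSpec(500, 250))
        assert (df["theta_w"] == 0).all()

    def test_short_alignment_truncated_window(self):
        aln = HaplotypeAlignment(ids=list("ab"), seqs=["ACGT" * 25] * 2)
        df = sliding_windows(aln, WindowSpec(500, 250))
        assert len(df) == 1
        assert df["end"].iloc[0] == 100

    def test_window_average_matches_whole_locus(self):
        aln, _ = make_alignment(
            SynthSpec(scenario="neutral-constant", n=10, theta=30.0, locus_length=4000, seed=6)
        )
        df = sliding_windows(aln, WindowSpec(500, 500))
        whole = summary_stats(aln)
        win_avg = np.average(
            df["theta_w"].to_numpy(), weights=df["n_sites_used"].to_numpy()
        )
        assert win_avg == pytest.approx(whole.theta_w, rel=0.05)

    def test_sweep_alignment_has_central_trough(self):
        # average over replicates: diversity dips at the sweep position
        centre, edge = [], []
        for seed in range(12):
            aln, _ = make_alignment(
                SynthSpec(scenario="sweep", n=12, theta=12.0, locus_length=3000,
                          sweep_alpha=2e-3, seed=seed)
            )
            df = sliding_windows(aln, WindowSpec(500, 500))
            mid = df["start"].sub(1500).abs().idxmin()
            centre.append(df.loc[mid, "pi"])
            edge.append(df["pi"].iloc[[0, -1]].mean())
        assert np.mean(centre) < np.mean(edge)


class TestNeutralSimulationMoments:
    def test_mean_pi_matches_theta(self):
        pis = []
        for rep in simulate_replicates(10, 2000, theta=5.0, seed=8):
            pis.append(_pi_from_matrix(rep.haplotypes))
        se = np.std(pis) / np.sqrt(len(pis))
        assert abs(np.mean(pis) - 5.0) < 2 * se + 1e-9
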