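import numpy as np
import pytest

from indelsweep.clr import (
    ClrSweepScan,
    SiteFrequencySpectrum,
    SweepSpectrumTransform,
    background_sfs,
    calibrate_threshold,
    invariant_lattice,
    neutral_sfs,
    sweep_sfs,
)
from indelsweep.coalescent import simulate_replicates
from indelsweep.synth import SynthSpec, make_sweep_sites


@pytest.fixture(scope="module")
def bg12():
    return neutral_sfs(12, 0.0023, 6000)


class TestBackgroundSFS:
    def test_all_invariant_concentrates_on_class_zero(self):
        sfs = background_sfs([0] * 100, n=4)
        assert np.argmax(sfs.probs) == 0
        # smoothing adds one pseudo-count to each empty class
        assert sfs.probs[0] == pytest.approx(100 / 104)

    def test_uniform_counts_give_uniform_probs(self):
        sfs = background_sfs(list(range(5)) * 10, n=4)
        assert np.allclose(sfs.probs, 0.2)

    def test_all_zero_table_errors(self):
        with pytest.raises(ValueError):
            SiteFrequencySpectrum.from_counts([0, 0, 0])

    def test_neutral_simulation_matches_watterson_shape(self):
        counts = np.zeros(13)
        for rep in simulate_replicates(12, 400, theta=5.0, seed=0):
            c = rep.haplotypes.sum(axis=0)
            np.add.at(counts, c, 1)
        freq = counts[1:12]
        expected = (1 / np.arange(1, 12))
        expected = expected / expected.sum() * freq.sum()
        # shape comparison: correlation of observed and 1/i expectation
        assert np.corrcoef(freq, expected)[0, 1] > 0.98

    def test_fold_collapses_mirror_classes(self):
        probs = np.arange(1.0, 6.0)
        probs /= probs.sum()
        sfs = SiteFrequencySpectrum(4, probs)
        folded = sfs.fold()
        assert folded.probs[0] == pytest.approx(probs[0] + probs[4])
        assert folded.probs.sum() == pytest.approx(1.0)


class TestSweepSpectrum:
    def test_escape_limit_returns_background(self, bg12):
        out = sweep_sfs(bg12, alpha=10.0, d=1e6)
        assert np.allclose(out.probs, bg12.probs, atol=1e-9)

    def test_total_sweep_limit_degenerate_classes(self, bg12):
        out = SweepSpectrumTransform(bg12).spectrum(0.0)
        support = set(np.flatnonzero(out > 1e-12))
        assert support <= {0, 1, bg12.n - 1, bg12.n}

    @pytest.mark.parametrize("pe", [0.0, 0.05, 0.3, 0.7, 0.95, 1.0])
    def test_mass_conservation(self, bg12, pe):
        out = SweepSpectrumTransform(bg12).spectrum(pe)
        assert abs(out.sum() - 1.0) < 1e-9

    def test_random_backgrounds_conserve_mass(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            probs = rng.dirichlet(np.ones(9))
            bg = SiteFrequencySpectrum(8, probs)
            pe = rng.random()
            out = SweepSpectrumTransform(bg).spectrum(pe)
            assert abs(out.sum() - 1.0) < 1e-9

    def test_folded_background_rejected(self, bg12):
        with pytest.raises(ValueError):
            sweep_sfs(bg12.fold(), alpha=1e-3, d=100)

    def test_symmetry_preserved(self):
        probs = np.ones(13)
        probs[0] = probs[12] = 40
        bg = SiteFrequencySpectrum(12, probs / probs.sum())
        tr = SweepSpectrumTransform(bg)
        for pe in (0.0, 0.4, 0.8):
            s = tr.spectrum(pe)
            assert np.allclose(s, s[::-1], atol=1e-12)


class TestScan:
    def test_lambda_nonnegative_and_order_invariant(self, bg12):
        rng = np.random.default_rng(2)
        pos = rng.uniform(0, 6000, 500)
        counts = rng.choice(13, 500, p=bg12.probs)
        res = ClrSweepScan(pos, counts, bg12).fit()
        assert (res.table["lambda"] >= 0).all()
        perm = rng.permutation(500)
        res2 = ClrSweepScan(pos[perm], counts[perm], bg12).fit()
        assert np.allclose(
            res.table["lambda"].to_numpy(), res2.table["lambda"].to_numpy()
        )

    def test_background_data_gives_small_lambda(self, bg12):
        rng = np.random.default_rng(3)
        pos = rng.uniform(0, 6000, 10_000)
        counts = rng.choice(13, 10_000, p=bg12.probs)
        res = ClrSweepScan(pos, counts, bg12).fit()
        # self-consistency: no sweep signal in iid background draws
        assert res.table["lambda"].max() < 8.0
        assert res.table["lambda"].median() < 2.0

    def test_invariant_sites_carry_weight(self, bg12):
        rng = np.random.default_rng(4)
        snp_pos = rng.uniform(0, 6000, 60)
        snp_counts = rng.integers(1, 12, 60)
        inv_pos, inv_counts, inv_w = invariant_lattice(6000, 5000, 12)
        with_inv = ClrSweepScan(
            np.concatenate([snp_pos, inv_pos]),
            np.concatenate([snp_counts, inv_counts]),
            bg12,
            weights=np.concatenate([np.ones(60), inv_w]),
            span=(0, 6000),
        ).fit()
        without = ClrSweepScan(
            snp_pos, snp_counts, bg12, span=(0, 6000)
        ).fit()
        assert not np.allclose(
            with_inv.table["lambda"].to_numpy(), without.table["lambda"].to_numpy()
        )

    def test_sweep_recovery_position_and_alpha(self, bg12):
        spec = SynthSpec(scenario="sweep", sweep_alpha=1e-3, seed=11)
        sites = make_sweep_sites(spec, bg=bg12)
        res = ClrSweepScan(
            sites.position.to_numpy(float),
            sites.derived_count.to_numpy(),
            bg12,
        ).fit()
        assert abs(res.peak_position - 3000) <= 2000
        assert 5e-4 <= res.alpha_hat <= 2e-3

    def test_folded_and_unfolded_agree_on_symmetric_spectrum(self):
        probs = np.ones(13)
        probs[0] = probs[12] = 30
        bg = SiteFrequencySpectrum(12, probs / probs.sum())
        rng = np.random.default_rng(5)
        pos = rng.uniform(0, 4000, 800)
        counts = rng.choice(13, 800, p=bg.probs)
        lam_u = ClrSweepScan(pos, counts, bg).fit().table["lambda"]
        lam_f = ClrSweepScan(pos, counts, bg, folded=True).fit().table["lambda"]
        assert np.allclose(lam_u.to_numpy(), lam_f.to_numpy(), atol=0.02)

    def test_empty_site_list_errors(self, bg12):
        with pytest.raises(ValueError):
            ClrSweepScan(np.array([]), np.array([]), bg12)

    def test_summary_reports_peak(self, bg12):
        rng = np.random.default_rng(6)
        pos = rng.uniform(0, 3000, 200)
        counts = rng.choice(13, 200, p=bg12.probs)
        res = ClrSweepScan(pos, counts, bg12).fit(threshold=5.0)
        assert "peak position" in res.summary()
        assert "threshold" in res.summary()


class TestCalibration:
    def test_threshold_monotone_in_quantile_and_reproducible(self, bg12):
        cal = calibrate_threshold(
            bg12, locus_length=6000, theta=10.0, reps=120, seed=7
        )
        cal2 = calibrate_threshold(
            bg12, locus_length=6000, theta=10.0, reps=120, seed=7
        )
        assert np.array_equal(cal.max_lambdas, cal2.max_lambdas)
        q = [np.quantile(cal.max_lambdas, x) for x in (0.5, 0.9, 0.95)]
        assert q == sorted(q)
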