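import io

import numpy as np
import pytest
from scipy import stats

from indelsweep.coalescent import (
    ConfigError,
    DemographicModel,
    Epoch,
    drop_mutations_fixed_s,
    drop_mutations_theta,
    simulate_genealogy,
    simulate_replicates,
    write_ms,
)
from indelsweep.datasets import demographic_model


def _four_gamete_fails(hap: np.ndarray) -> bool:
    S = hap.shape[1]
    for i in range(S):
        for j in range(i + 1, S):
            pats = {tuple(p) for p in hap[:, [i, j]]}
            if len(pats) == 4:
                return True
    return False


class TestDemographicModel:
    def test_non_increasing_epochs_rejected(self):
        with pytest.raises(ConfigError):
            DemographicModel(name="bad", epochs=[Epoch(0.0, 1.0), Epoch(0.0, 0.5)])

    def test_first_epoch_must_start_at_zero(self):
        with pytest.raises(ConfigError):
            DemographicModel(name="bad", epochs=[Epoch(0.1, 1.0)])

    def test_named_models_load(self):
        for name in ("constant", "duchen", "werzner", "thornton-andolfatto"):
            m = demographic_model(name)
            assert m.epochs[0].time == 0.0

    def test_yaml_round_trip(self, tmp_path):
        p = tmp_path / "m.yaml"
        p.write_text("name: toy\nepochs:\n  - [0.0, 1.0]\n  - [0.1, 0.02]\n")
        m = DemographicModel.from_yaml(p)
        assert m.size_at(0.05) == 1.0
        assert m.size_at(0.2) == 0.02


class TestGenealogy:
    def test_mean_tmrca_n2_is_half(self):
        rng = np.random.default_rng(0)
        tm = [simulate_genealogy(2, rng=rng).tmrca for _ in range(4000)]
        se = np.std(tm) / np.sqrt(len(tm))
        assert abs(np.mean(tm) - 0.5) < 2 * se

    def test_mean_tmrca_n10(self):
        rng = np.random.default_rng(1)
        tm = [simulate_genealogy(10, rng=rng).tmrca for _ in range(3000)]
        se = np.std(tm) / np.sqrt(len(tm))
        assert abs(np.mean(tm) - 0.9) < 2.5 * se

    def test_doubling_size_doubles_tmrca(self):
        rng = np.random.default_rng(2)
        big = DemographicModel.constant(2.0)
        tm1 = np.mean([simulate_genealogy(6, rng=rng).tmrca for _ in range(2500)])
        tm2 = np.mean(
            [simulate_genealogy(6, big, rng=rng).tmrca for _ in range(2500)]
        )
        assert tm2 / tm1 == pytest.approx(2.0, rel=0.1)

    def test_bottleneck_shortens_tmrca(self):
        bott = DemographicModel(
            name="bott", epochs=[Epoch(0.0, 1.0), Epoch(0.02, 0.01), Epoch(0.1, 1.0)]
        )
        rng = np.random.default_rng(3)
        t_const = np.mean([simulate_genealogy(10, rng=rng).tmrca for _ in range(1500)])
        t_bott = np.mean(
            [simulate_genealogy(10, bott, rng=rng).tmrca for _ in range(1500)]
        )
        assert t_bott < t_const

    def test_seeded_runs_bit_reproducible(self):
        a = simulate_genealogy(8, rho=2.0, seed=99)
        b = simulate_genealogy(8, rho=2.0, seed=99)
        assert a.tmrca == b.tmrca
        assert [(l, r) for l, r, _ in a.intervals] == [
            (l, r) for l, r, _ in b.intervals
        ]

    def test_intervals_tile_unit_interval_with_recombination(self):
        g = simulate_genealogy(8, rho=5.0, seed=7)
        lefts = [l for l, _, _ in g.intervals]
        rights = [r for _, r, _ in g.intervals]
        assert lefts[0] == 0.0
        assert rights[-1] == 1.0
        assert all(
            r1 == pytest.approx(l2) for r1, l2 in zip(rights[:-1], lefts[1:])
        )


class TestMutations:
    def test_theta_mode_mean_segsites(self):
        S = [r.segsites for r in simulate_replicates(10, 3000, theta=5.0, seed=4)]
        se = np.std(S) / np.sqrt(len(S))
        assert abs(np.mean(S) - 5.0 * sum(1 / i for i in range(1, 10))) < 2 * se

    def test_theta_zero_no_sites(self):
        g = simulate_genealogy(6, seed=5)
        assert drop_mutations_theta(g, 0.0, seed=0).segsites == 0

    def test_infinite_sites_invariant(self):
        for rep in simulate_replicates(8, 50, theta=6.0, rho=1.0, seed=6):
            if rep.segsites:
                counts = rep.haplotypes.sum(axis=0)
                assert counts.min() >= 1 and counts.max() <= 7

    def test_fixed_s_exact_column_count(self):
        for rep in simulate_replicates(12, 50, fixed_s=41, seed=7):
            assert rep.segsites == 41

    def test_fixed_s_zero_empty_matrix(self):
        g = simulate_genealogy(5, seed=8)
        rep = drop_mutations_fixed_s(g, 0, seed=0)
        assert rep.haplotypes.shape == (5, 0)

    def test_branch_choice_proportional_to_length(self):
        g = simulate_genealogy(6, seed=9)
        rep = drop_mutations_fixed_s(g, 20000, seed=10)
        root = g.root
        # tally observed mutations per branch vs expected share
        from collections import Counter

        obs = Counter(rep.mutation_nodes)
        nodes, lengths = [], []
        stack = [root]
        while stack:
            v = stack.pop()
            for c in v.children:
                nodes.append(c)
                lengths.append(v.time - c.time)
                stack.append(c)
        lengths = np.array(lengths)
        expected = 20000 * lengths / lengths.sum()
        observed = np.array([obs.get(nd, 0) for nd in nodes])
        keep = expected >= 5
        chi2 = stats.chisquare(observed[keep], expected[keep] * observed[keep].sum() / expected[keep].sum())
        assert chi2.pvalue > 1e-3


class TestRecombination:
    def test_no_recombination_single_tree_no_four_gamete_failure(self):
        for rep in simulate_replicates(8, 40, theta=8.0, rho=0.0, seed=11):
            assert not _four_gamete_fails(rep.haplotypes)

    def test_recombination_creates_four_gamete_failures(self):
        fails = sum(
            _four_gamete_fails(rep.haplotypes)
            for rep in simulate_replicates(10, 60, theta=10.0, rho=10.0, seed=12)
        )
        assert fails > 0

    def test_mean_segsites_unchanged_by_rho(self):
        S0 = [r.segsites for r in simulate_replicates(10, 1500, theta=5.0, seed=13)]
        S5 = [
            r.segsites
            for r in simulate_replicates(10, 1500, theta=5.0, rho=5.0, seed=14)
        ]
        se = np.sqrt(np.var(S0) / len(S0) + np.var(S5) / len(S5))
        assert abs(np.mean(S0) - np.mean(S5)) < 3 * se


class TestCrossValidation:
    def test_mean_segsites_matches_msprime(self):
        """Independent oracle: same scaled model run through msprime."""
        msprime = pytest.importorskip("msprime")
        S_ms = []
        for ts in msprime.sim_ancestry(
            samples=5,
            ploidy=2,
            sequence_length=1,
            population_size=0.25,
            num_replicates=600,
            random_seed=7,
        ):
            mts = msprime.sim_mutations(ts, rate=5.0, discrete_genome=False)
            S_ms.append(mts.num_sites)
        S_own = [
            r.segsites for r in simulate_replicates(10, 600, theta=5.0, seed=15)
        ]
        se = np.sqrt(np.var(S_ms) / len(S_ms) + np.var(S_own) / len(S_own))
        assert abs(np.mean(S_ms) - np.mean(S_own)) < 3 * se


def test_ms_format_output():
    reps = list(simulate_replicates(4, 2, fixed_s=3, seed=16))
    buf = io.StringIO()
    write_ms(reps, buf)
    text = buf.getvalue()
    assert text.count("//") == 2
    assert "segsites: 3" in text
    rows = [l for l in text.splitlines() if set(l) <= {"0", "1"} and l]
    assert len(rows) == 8
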