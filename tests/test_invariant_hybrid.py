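"""Invariant hybrid test: pattern tabulation, gamma recovery, search."""

from itertools import product

import numpy as np
import pytest

from introscan.containers import PopulationMap
from introscan.invariant_hybrid import (
    full_search,
    hybrid_test,
    individual_tests,
    quartet_patterns,
)
from introscan.simdata import SimulationConfig, simulate_dataset
from introscan.trio_stats import population_frequencies

from conftest import make_gm


def quartet_gm(fo, f1, fh, f2, n_per_group=2):
    """Matrix whose per-group frequencies are exactly as given: each group
    holds identical homozygous-scaled samples (frequencies 0, 0.5, 1)."""
    cols = []
    for site in range(len(fo)):
        col = []
        for f in (fo[site], f1[site], fh[site], f2[site]):
            col.extend([2.0 * f] * n_per_group)
        cols.append(col)
    dosage = np.array(cols).T
    samples = [f"{g}_{i}" for g in ("O", "A", "H", "B") for i in range(n_per_group)]
    gm = make_gm(dosage, samples=samples)
    pm = PopulationMap(assignments={s: s.split("_")[0] for s in samples})
    return gm, pm


class TestQuartetPatterns:
    def test_monomorphic_mass_on_constant_pattern(self):
        gm, pm = quartet_gm([0, 0], [0, 0], [0, 0], [0, 0])
        counts = quartet_patterns(gm, pm, ("O", "A", "H", "B"))
        assert counts.mass[0] == pytest.approx(2.0)
        assert counts.mass[1:].sum() == pytest.approx(0.0)

    def test_forced_pattern_h_and_p2_derived(self):
        gm, pm = quartet_gm([0], [0], [1], [1])
        counts = quartet_patterns(gm, pm, ("O", "A", "H", "B"))
        # pattern bits (O,P1,H,P2) = (0,0,1,1) -> index 3
        assert counts.mass[3] == pytest.approx(1.0)
        assert counts.mass.sum() == pytest.approx(1.0)

    def test_matches_exhaustive_enumeration_oracle(self):
        """Vectorized masses equal a brute-force enumeration over all 16
        ancestral/derived assignments at each site, with each group's
        derived probability taken from its observed allele frequency."""
        rng = np.random.default_rng(42)
        n_sites, per_group = 100, 3
        dosage = rng.integers(0, 3, size=(4 * per_group, n_sites)).astype(float)
        samples = [
            f"{g}_{i}" for g in ("O", "A", "H", "B") for i in range(per_group)
        ]
        gm = make_gm(dosage, samples=samples)
        pm = PopulationMap(assignments={s: s.split("_")[0] for s in samples})
        counts = quartet_patterns(gm, pm, ("O", "A", "H", "B"))
        group_freqs = [
            dosage[3 * k : 3 * (k + 1)].mean(axis=0) / 2.0 for k in range(4)
        ]
        expected = np.zeros(16)
        for site in range(n_sites):
            fs = [f[site] for f in group_freqs]
            for states in product((0, 1), repeat=4):
                prob = 1.0
                for f, s in zip(fs, states):
                    prob *= f if s else 1.0 - f
                idx = states[0] * 8 + states[1] * 4 + states[2] * 2 + states[3]
                expected[idx] += prob
        np.testing.assert_allclose(counts.mass, expected, rtol=1e-10)

    def test_mass_conservation_is_exact(self, hybrid_dataset):
        gm, _, pm = hybrid_dataset
        counts = quartet_patterns(gm, pm, ("OUT", "P1", "HYB", "P2"))
        assert counts.mass.sum() == pytest.approx(counts.n_sites, rel=1e-12)


class TestHybridTest:
    def test_f1_population_gamma_half(self):
        cfg = SimulationConfig(
            n_sites=50_000,
            pop_sizes={"P1": 8, "P2": 8, "HYB": 4, "OUT": 2},
            gamma_per_individual={f"HYB_{i}": 0.5 for i in (1, 2, 3, 4)},
            seed=31,
        )
        gm, _, pm = simulate_dataset(cfg)
        res = hybrid_test(quartet_patterns(gm, pm, ("OUT", "P1", "HYB", "P2")))
        assert res.gamma == pytest.approx(0.5, abs=0.05)

    def test_mixed_population_gamma_quarter(self, hybrid_dataset):
        """2 F1 + 2 pure-P1 individuals give a population gamma of 0.25."""
        gm, _, pm = hybrid_dataset
        res = hybrid_test(quartet_patterns(gm, pm, ("OUT", "P1", "HYB", "P2")))
        assert res.gamma == pytest.approx(0.25, abs=0.05)

    def test_pure_p1_copies_not_significant_or_near_zero(self):
        cfg = SimulationConfig(
            n_sites=30_000,
            pop_sizes={"P1": 8, "P2": 8, "HYB": 4, "OUT": 2},
            gamma_per_individual={f"HYB_{i}": 0.0 for i in (1, 2, 3, 4)},
            seed=32,
        )
        gm, _, pm = simulate_dataset(cfg)
        res = hybrid_test(quartet_patterns(gm, pm, ("OUT", "P1", "HYB", "P2")))
        assert (not np.isfinite(res.p)) or res.p > 0.01 or abs(res.gamma) < 0.05

    def test_swap_of_parents_reflects_gamma_exactly(self, hybrid_dataset):
        gm, _, pm = hybrid_dataset
        fwd = hybrid_test(quartet_patterns(gm, pm, ("OUT", "P1", "HYB", "P2")))
        rev = hybrid_test(quartet_patterns(gm, pm, ("OUT", "P2", "HYB", "P1")))
        assert fwd.gamma == pytest.approx(1.0 - rev.gamma, abs=1e-12)

    def test_gamma_monotone_in_truth_and_agrees_with_ls_oracle(self):
        """Across a gamma grid the estimate is rank-perfect and within
        0.05 of the independent least-squares mixture estimator."""
        grid = [0.1, 0.3, 0.5, 0.7, 0.9]
        estimates, ls_estimates = [], []
        for i, g in enumerate(grid):
            cfg = SimulationConfig(
                n_sites=50_000,
                pop_sizes={"P1": 100, "P2": 100, "HYB": 20, "OUT": 2},
                gamma_per_individual={f"HYB_{k}": g for k in range(1, 21)},
                seed=40 + i,
            )
            gm, _, pm = simulate_dataset(cfg)
            res = hybrid_test(quartet_patterns(gm, pm, ("OUT", "P1", "HYB", "P2")))
            estimates.append(res.gamma)
            freqs = population_frequencies(gm, pm)
            p1, p2, ph = freqs.freqs["P1"], freqs.freqs["P2"], freqs.freqs["HYB"]
            ok = np.isfinite(p1) & np.isfinite(p2) & np.isfinite(ph)
            num = np.sum((ph[ok] - p1[ok]) * (p2[ok] - p1[ok]))
            den = np.sum((p2[ok] - p1[ok]) ** 2)
            ls_estimates.append(num / den)
        assert estimates == sorted(estimates)
        for est, ls in zip(estimates, ls_estimates):
            assert est == pytest.approx(ls, abs=0.05)


class TestIndividualTests:
    def test_recovers_per_individual_gammas(self):
        truth = {"HYB_1": 0.5, "HYB_2": 0.2, "HYB_3": 0.0}
        cfg = SimulationConfig(
            n_sites=50_000,
            pop_sizes={"P1": 8, "P2": 8, "HYB": 3, "OUT": 2},
            gamma_per_individual=truth,
            seed=33,
        )
        gm, _, pm = simulate_dataset(cfg)
        results = individual_tests(gm, pm, ("P1", "HYB", "P2"), "OUT")
        by_sample = {r.hybrid: r.gamma for r in results}
        for sample, g in truth.items():
            assert by_sample[sample] == pytest.approx(g, abs=0.07)

    def test_deterministic_for_identical_input(self, hybrid_dataset):
        gm, _, pm = hybrid_dataset
        a = individual_tests(gm, pm, ("P1", "HYB", "P2"), "OUT")
        b = individual_tests(gm, pm, ("P1", "HYB", "P2"), "OUT")
        assert [r.gamma for r in a] == [r.gamma for r in b]

    def test_all_missing_individual_is_an_error(self):
        dosage = np.array(
            [
                [0.0, 0.0], [0.0, 0.0],      # OUT
                [0.0, 2.0], [0.0, 2.0],      # P1
                [np.nan, np.nan],            # hybrid, nothing called
                [2.0, 0.0], [2.0, 0.0],      # P2
            ]
        )
        samples = ["O_1", "O_2", "A_1", "A_2", "H_1", "B_1", "B_2"]
        gm = make_gm(dosage, samples=samples)
        pm = PopulationMap(assignments={s: s.split("_")[0] for s in samples})
        with pytest.raises(ValueError, match="no called genotypes"):
            individual_tests(gm, pm, ("A", "H", "B"), "O")

    def test_low_confidence_flag_on_sparse_individual(self):
        rng = np.random.default_rng(7)
        n = 400
        dosage = np.vstack(
            [
                np.zeros((2, n)),                        # OUT
                rng.integers(0, 3, (3, n)).astype(float),  # P1
                np.where(rng.random(n) < 0.8, np.nan, 1.0)[np.newaxis],  # hybrid
                rng.integers(0, 3, (3, n)).astype(float),  # P2
            ]
        )
        samples = ["O_1", "O_2", "A_1", "A_2", "A_3", "H_1", "B_1", "B_2", "B_3"]
        gm = make_gm(dosage, samples=samples)
        pm = PopulationMap(assignments={s: s.split("_")[0] for s in samples})
        (res,) = individual_tests(gm, pm, ("A", "H", "B"), "O")
        assert res.low_confidence


class TestFullSearch:
    def test_arrangement_count_for_four_candidates(self, geneflow_dataset):
        gm, _, pm = geneflow_dataset
        table = full_search(gm, pm, "OUT", filtered=False)
        assert len(table) == 12  # 3 hybrid roles x C(4,3) trios

    def test_null_simulation_passes_nothing(self):
        hits = 0
        for seed in range(10):
            cfg = SimulationConfig(
                n_sites=10_000,
                pop_sizes={"P1": 6, "P2": 6, "P3": 6, "P4": 6, "OUT": 2},
                drift={"P1": 0.1, "P2": 0.1, "P3": 0.1, "P4": 0.1, "P12": 0.05},
                seed=600 + seed,
            )
            gm, _, pm = simulate_dataset(cfg)
            if len(full_search(gm, pm, "OUT")) > 0:
                hits += 1
        assert hits == 0

    def test_true_hybrid_population_is_top_ranked(self):
        cfg = SimulationConfig(
            n_sites=30_000,
            pop_sizes={"P1": 6, "P2": 6, "P3": 6, "HYB": 4, "OUT": 2},
            gamma_per_individual={f"HYB_{i}": 0.5 for i in (1, 2, 3, 4)},
            seed=34,
        )
        gm, _, pm = simulate_dataset(cfg)
        table = full_search(gm, pm, "OUT")
        assert len(table) > 0
        assert table.iloc[0]["Hybrid"] == "HYB"
        assert {table.iloc[0]["P1"], table.iloc[0]["P2"]} == {"P1", "P2"}
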