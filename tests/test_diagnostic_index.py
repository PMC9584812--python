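"""Diagnostic fixed-difference sites, hybrid index, region means, FDR."""

import numpy as np
import pytest

from introscan.containers import FrequencyTable, PopulationMap
from introscan.diagnostic_index import (
    aggregate_by_region,
    estimate_fdr,
    find_diagnostic_sites,
    hybrid_index,
)
from introscan.simdata import SimulationConfig, simulate_genotypes

from conftest import make_gm

import pandas as pd


def panel_gm(site_specs, extra_rows=None, qual=50.0):
    """Build a matrix with 2 panel-A and 2 panel-B samples per site_specs.

    site_specs: list of (dosA, dosB) pairs applied to both members of
    each panel; extra_rows: dict sample -> list of dosages.
    """
    extra = extra_rows or {}
    n_sites = len(site_specs)
    rows = {
        "A1": [s[0] for s in site_specs],
        "A2": [s[0] for s in site_specs],
        "B1": [s[1] for s in site_specs],
        "B2": [s[1] for s in site_specs],
    }
    rows.update(extra)
    dosage = np.array([rows[k] for k in rows], dtype=float)
    return make_gm(dosage, samples=list(rows), qual=qual), list(rows)


class TestFindDiagnosticSites:
    def test_fixed_opposite_homozygotes_included(self):
        gm, _ = panel_gm([(0.0, 2.0)])
        sites = find_diagnostic_sites(gm, ["A1", "A2"], ["B1", "B2"])
        assert len(sites) == 1
        row = sites.table.iloc[0]
        assert (row["alleleA"], row["alleleB"]) == ("A", "T")

    def test_panel_a_need_not_be_ref(self):
        gm, _ = panel_gm([(2.0, 0.0)])
        sites = find_diagnostic_sites(gm, ["A1", "A2"], ["B1", "B2"])
        assert sites.table.iloc[0]["alleleA"] == "T"

    def test_heterozygous_panel_member_excludes_site(self):
        gm, _ = panel_gm([(0.0, 2.0)], extra_rows=None)
        gm.dosage[0, 0] = 1.0  # A1 het
        assert len(find_diagnostic_sites(gm, ["A1", "A2"], ["B1", "B2"])) == 0

    def test_missing_panel_call_excludes_site(self):
        gm, _ = panel_gm([(0.0, 2.0)])
        gm.dosage[2, 0] = np.nan
        assert len(find_diagnostic_sites(gm, ["A1", "A2"], ["B1", "B2"])) == 0

    def test_low_qual_excludes_site(self):
        gm, _ = panel_gm([(0.0, 2.0)], qual=29.0)
        assert len(find_diagnostic_sites(gm, ["A1", "A2"], ["B1", "B2"])) == 0

    def test_overlapping_panels_rejected(self):
        gm, _ = panel_gm([(0.0, 2.0)])
        with pytest.raises(ValueError, match="overlap"):
            find_diagnostic_sites(gm, ["A1", "A2"], ["A2", "B1"])

    def test_adding_panel_samples_only_shrinks_the_set(self):
        rng = np.random.default_rng(3)
        dosage = rng.choice([0.0, 1.0, 2.0], size=(8, 500))
        samples = [f"A{i}" for i in range(1, 5)] + [f"B{i}" for i in range(1, 5)]
        gm = make_gm(dosage, samples=samples)
        small = find_diagnostic_sites(gm, ["A1", "A2"], ["B1", "B2"])
        large = find_diagnostic_sites(gm, ["A1", "A2", "A3"], ["B1", "B2", "B3"])
        small_keys = set(map(tuple, small.table[["chrom", "pos"]].to_numpy()))
        large_keys = set(map(tuple, large.table[["chrom", "pos"]].to_numpy()))
        assert large_keys <= small_keys


class TestHybridIndex:
    def test_panel_members_score_exactly_one_and_zero(self):
        gm, _ = panel_gm([(0.0, 2.0), (2.0, 0.0), (0.0, 2.0)])
        sites = find_diagnostic_sites(gm, ["A1", "A2"], ["B1", "B2"])
        assert hybrid_index(gm, sites, "A1").frac_a == 1.0
        assert hybrid_index(gm, sites, "B2").frac_a == 0.0

    def test_hand_count_three_homA_two_het_five_homB(self):
        specs = [(0.0, 2.0)] * 10
        target = [0.0] * 3 + [1.0] * 2 + [2.0] * 5  # dosage 0 = A allele here
        gm, _ = panel_gm(specs, extra_rows={"T1": target})
        sites = find_diagnostic_sites(gm, ["A1", "A2"], ["B1", "B2"])
        res = hybrid_index(gm, sites, "T1")
        assert res.n_sites_called == 10
        assert res.frac_a == pytest.approx((6 + 2) / 20)  # 0.4

    def test_missing_sites_excluded_from_both_sides(self):
        specs = [(0.0, 2.0)] * 4
        gm, _ = panel_gm(specs, extra_rows={"T1": [0.0, np.nan, 2.0, np.nan]})
        sites = find_diagnostic_sites(gm, ["A1", "A2"], ["B1", "B2"])
        res = hybrid_index(gm, sites, "T1")
        assert res.n_sites_called == 2
        assert res.frac_a == 0.5

    def test_zero_called_sites_is_an_error(self):
        specs = [(0.0, 2.0)]
        gm, _ = panel_gm(specs, extra_rows={"T1": [np.nan]})
        sites = find_diagnostic_sites(gm, ["A1", "A2"], ["B1", "B2"])
        with pytest.raises(ValueError, match="no called genotypes"):
            hybrid_index(gm, sites, "T1")

    def test_per_genotype_mode_uses_homozygous_calls_only(self):
        specs = [(0.0, 2.0)] * 4
        gm, _ = panel_gm(specs, extra_rows={"T1": [0.0, 1.0, 1.0, 2.0]})
        sites = find_diagnostic_sites(gm, ["A1", "A2"], ["B1", "B2"])
        res = hybrid_index(gm, sites, "T1", per_genotype=True)
        assert res.n_sites_called == 2
        assert res.frac_a == 0.5

    def test_expected_index_equals_gamma_with_small_bias(self):
        """E[fracB] = gamma across the grid; bias < 0.01 with 10,000
        fully diagnostic sites (fixed difference at every locus)."""
        n = 10_000
        ft = FrequencyTable(freqs={"P1": np.zeros(n), "P2": np.ones(n)})
        grid = {f"HYB_{i}": g for i, g in enumerate(
            (0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9), start=1)}
        cfg = SimulationConfig(
            n_sites=n,
            pop_sizes={"P1": 4, "P2": 4, "HYB": 9},
            gamma_per_individual=grid,
            qual_law=("constant", 60.0),
            seed=55,
        )
        gm, _ = simulate_genotypes(ft, cfg)
        sites = find_diagnostic_sites(
            gm, [f"P1_{i}" for i in (1, 2, 3, 4)], [f"P2_{i}" for i in (1, 2, 3, 4)]
        )
        assert len(sites) == n
        errors = [
            hybrid_index(gm, sites, s).frac_b - g for s, g in grid.items()
        ]
        assert abs(np.mean(errors)) < 0.01
        assert max(abs(e) for e in errors) < 0.03


class TestRegions:
    def test_single_sample_region_mean_is_sample_value(self):
        results = pd.DataFrame({"sample": ["s1"], "frac_a": [0.7]})
        meta = pd.DataFrame({"sample": ["s1"], "region": ["wales"]})
        out = aggregate_by_region(results, meta)
        assert out.loc[0, "mean_frac_a"] == 0.7
        assert out.loc[0, "n_samples"] == 1

    def test_two_sample_region_mean(self):
        results = pd.DataFrame(
            {"sample": ["s1", "s2"], "frac_a": [0.2, 0.4]}
        )
        meta = pd.DataFrame(
            {"sample": ["s1", "s2"], "region": ["x", "x"]}
        )
        out = aggregate_by_region(results, meta)
        assert out.loc[0, "mean_frac_a"] == pytest.approx(0.3)

    def test_sample_without_region_excluded_with_warning(self):
        results = pd.DataFrame({"sample": ["s1", "s2"], "frac_a": [0.2, 0.4]})
        meta = pd.DataFrame({"sample": ["s1"], "region": ["x"]})
        with pytest.warns(UserWarning, match="without region"):
            out = aggregate_by_region(results, meta)
        assert len(out) == 1

    def test_gamma_gradient_produces_monotone_region_means(self):
        n = 5000
        ft = FrequencyTable(freqs={"P1": np.zeros(n), "P2": np.ones(n)})
        grid = {f"HYB_{i}": 0.2 * i for i in range(1, 5)}
        cfg = SimulationConfig(
            n_sites=n,
            pop_sizes={"P1": 2, "P2": 2, "HYB": 4},
            gamma_per_individual=grid,
            region_labels={f"HYB_{i}": f"r{i}" for i in range(1, 5)},
            qual_law=("constant", 60.0),
            seed=56,
        )
        gm, truth = simulate_genotypes(ft, cfg)
        sites = find_diagnostic_sites(gm, ["P1_1", "P1_2"], ["P2_1", "P2_2"])
        results = pd.DataFrame(
            {
                "sample": list(grid),
                "frac_a": [hybrid_index(gm, sites, s).frac_a for s in grid],
            }
        )
        meta = truth[["sample", "region"]]
        out = aggregate_by_region(results, meta).sort_values("region")
        assert out["mean_frac_a"].is_monotonic_decreasing


class TestFdr:
    def test_arithmetic(self):
        # 50 sites x 1 sample = 100 allele copies, one het = 1 discordant
        specs = [(0.0, 2.0)] * 50
        target = [0.0] * 49 + [1.0]
        gm, _ = panel_gm(specs, extra_rows={"V1": target})
        sites = find_diagnostic_sites(gm, ["A1", "A2"], ["B1", "B2"])
        est = estimate_fdr(gm.take_samples(["V1"]), sites, expected_panel="A")
        assert est.total_calls == 100
        assert est.discordant_calls == 1
        assert est.rate == pytest.approx(0.01)

    def test_panel_itself_has_zero_rate(self):
        specs = [(0.0, 2.0)] * 20
        gm, _ = panel_gm(specs)
        sites = find_diagnostic_sites(gm, ["A1", "A2"], ["B1", "B2"])
        est = estimate_fdr(gm.take_samples(["A1", "A2"]), sites, "A")
        assert est.rate == 0.0

    def test_injected_genotype_error_rate_recovered(self):
        rng = np.random.default_rng(9)
        n, eps = 20_000, 0.005
        specs = [(0.0, 2.0)] * n
        # flip each allele copy of a pure panel-A sample with prob eps
        noisy = (rng.random(n) < eps).astype(float) + (rng.random(n) < eps)
        gm, _ = panel_gm(specs, extra_rows={"V1": noisy.tolist()})
        sites = find_diagnostic_sites(gm, ["A1", "A2"], ["B1", "B2"])
        est = estimate_fdr(gm.take_samples(["V1"]), sites, "A")
        assert est.rate == pytest.approx(eps, abs=3 * np.sqrt(eps / (2 * n)))
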