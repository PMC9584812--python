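"""End-to-end orchestration: simulate (or load) -> filter -> trio D ->
invariant hybrid tests -> window scan -> diagnostic index -> pi/Fst ->
topology weighting -> adaptive-introgression intersection.

A single :class:`RunConfig` (YAML round-trippable) drives the run; the
global seed is fanned out per stage by hashing the stage name, so any
stage re-run from saved intermediates reproduces the full-run output.
Every stage writes a TSV with an explicit header; a ``summary.json``
collects the headline quantities and ``provenance.json`` records the
exact configuration and package version.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .containers import GenotypeMatrix, PopulationMap
from .diagnostic_index import aggregate_by_region, find_diagnostic_sites, hybrid_index
from .intersect_report import (
    genes_in_candidates,
    intersect_outliers_windows,
    merge_windows,
)
from .invariant_hybrid import full_search, individual_tests
from .popgen_summaries import fst_outliers, per_site_fst, windowed_pi
from .simdata import (
    SimulationConfig,
    simulate_dataset,
    write_population_map,
    write_simulated_vcf,
    write_truth_table,
)
from .topo_weights import enumerate_topologies, nj_window_tree, weight_tree
from .trio_stats import dtrios_all, population_frequencies
from .variant_io import (
    filter_biallelic_snps,
    filter_qual,
    read_gff_genes,
    read_population_map,
    read_vcf,
)
from .window_scan import scan_windows, top_percentile_windows

__all__ = ["RunConfig", "run_pipeline", "stage_seed"]

log = logging.getLogger("introscan")


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed: global seed mixed with a stage-name
    hash (always below 2**31)."""
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class RunConfig:
    """Serializable description of one pipeline run."""

    output_dir: str
    seed: int = 0
    # either a simulation block or input paths
    simulation: dict | None = None
    vcf: str | None = None
    popmap: str | None = None
    gff: str | None = None
    # population roles (labels); hybrid may be absent
    outgroup: str = "OUT"
    trio: tuple[str, str, str] | None = None  # (P1, P2, P3) for the scan
    hybrid_population: str | None = None
    diagnostic_panels: tuple[str, str] | None = None  # (panelA pop, panelB pop)
    # stage parameters (defaults as documented per module)
    min_qual: float = 30.0
    n_blocks: int = 20
    alpha: float = 0.05
    window_snps: int = 1000
    step_snps: int = 500
    top_pct: float = 1.0
    pi_window_bp: int = 100_000
    tree_window_snps: int = 250
    log_level: str = "INFO"

    def to_yaml(self, path) -> None:
        data = dataclasses.asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        for key in ("trio", "diagnostic_panels"):
            if data.get(key) is not None:
                data[key] = tuple(data[key])
        return cls(**data)


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def run_pipeline(config: RunConfig) -> dict:
    """Run every applicable stage; returns the summary dict.

    Stages without their required roles are skipped with a logged
    notice. Failures abort with the stage name in the exception message;
    partial outputs are left in place.
    """
    logging.basicConfig(level=config.log_level)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    summary: dict = {"seed": config.seed}
    stage = "setup"
    try:
        # ------------------------------------------------ input / simulate
        if config.simulation is not None:
            stage = "simulate"
            sim_cfg = SimulationConfig(
                **{**config.simulation, "seed": stage_seed(config.seed, "simulate")}
            )
            gm, truth, pm = simulate_dataset(sim_cfg)
            write_simulated_vcf(gm, out / "simulated.vcf")
            write_population_map(pm, out / "popmap.tsv")
            write_truth_table(truth, out / "truth.tsv")
            genes = None
        else:
            stage = "load"
            if not config.vcf or not config.popmap:
                raise ValueError("need either a simulation block or vcf+popmap")
            gm = read_vcf(config.vcf)
            pm = read_population_map(config.popmap)
            genes = read_gff_genes(config.gff) if config.gff else None

        # ------------------------------------------------------- filtering
        stage = "filter"
        gm = filter_biallelic_snps(gm)
        gm = filter_qual(gm, min_qual=config.min_qual)
        summary["n_sites_after_filters"] = gm.n_sites
        log.info("%d sites after biallelic+QUAL filters", gm.n_sites)

        pops = [p for p in pm.populations if p != config.outgroup]
        freqs = population_frequencies(gm, pm)

        # ---------------------------------------------------------- trios
        if len(pops) >= 3:
            stage = "dtrios"
            trios = dtrios_all(
                gm, pm, config.outgroup, n_blocks=config.n_blocks,
                seed=stage_seed(config.seed, "dtrios"),
            )
            _write(trios, out / "dtrios.tsv")
            summary["top_trio"] = trios.iloc[0][["P1", "P2", "P3", "D"]].to_dict()
        else:
            log.info("dtrios skipped: fewer than 3 non-outgroup populations")

        # ----------------------------------------------- hybrid detection
        if config.hybrid_population is not None:
            stage = "hyde"
            table = full_search(
                gm, pm, config.outgroup, alpha=config.alpha, filtered=False
            )
            _write(table, out / "hyde_full.tsv")
            parents = config.diagnostic_panels or _top_parents(
                table, config.hybrid_population
            )
            indiv = individual_tests(
                gm, pm, (parents[0], config.hybrid_population, parents[1]),
                config.outgroup,
            )
            indiv_df = pd.DataFrame(
                {
                    "P1": [r.p1 for r in indiv],
                    "Hybrid": [r.hybrid for r in indiv],
                    "P2": [r.p2 for r in indiv],
                    "Z": [r.z for r in indiv],
                    "p": [r.p for r in indiv],
                    "gamma": [r.gamma for r in indiv],
                }
            )
            _write(indiv_df, out / "hyde_individual.tsv")
            pop_rows = table[table["Hybrid"] == config.hybrid_population]
            if len(pop_rows):
                summary["population_gamma"] = float(pop_rows.iloc[0]["gamma"])
            summary["individual_gamma"] = dict(
                zip(indiv_df["Hybrid"], indiv_df["gamma"])
            )
        else:
            log.info("hybrid-test stage skipped: no hybrid population configured")

        # ------------------------------------------------ diagnostic index
        if config.diagnostic_panels is not None and config.hybrid_population:
            stage = "diagnostics"
            pa, pb = config.diagnostic_panels
            sites = find_diagnostic_sites(
                gm, pm.samples_in(pa), pm.samples_in(pb), min_qual=config.min_qual
            )
            sites.write_tsv(out / "diagnostic_sites.tsv")
            targets = pm.samples_in(config.hybrid_population)
            results = [hybrid_index(gm, sites, s) for s in targets]
            idx_df = pd.DataFrame(
                {
                    "sample": [r.sample for r in results],
                    "n_sites_called": [r.n_sites_called for r in results],
                    "frac_a": [r.frac_a for r in results],
                    "frac_b": [r.frac_b for r in results],
                }
            )
            _write(idx_df, out / "hybrid_index.tsv")
            summary["n_diagnostic_sites"] = len(sites)
        elif config.hybrid_population is None:
            log.info("diagnostics stage skipped: no hybrid population configured")

        # ------------------------------------------------------ window scan
        trio = config.trio
        if trio is not None:
            stage = "window_scan"
            wstats = scan_windows(
                freqs, trio, config.outgroup,
                window_snps=config.window_snps, step_snps=config.step_snps,
            )
            _write(wstats, out / "window_stats.tsv")
            top = top_percentile_windows(wstats, "f_dM", pct=config.top_pct)
            _write(top, out / "top_fdm_windows.tsv")
            summary["n_windows"] = len(wstats)
            summary["n_top_windows"] = len(top)

            stage = "fst"
            fst = per_site_fst(gm, pm, trio[0], trio[2])
            _write(fst, out / "fst.tsv")
            outl = fst_outliers(fst, pct=config.top_pct)
            _write(outl, out / "fst_outliers.tsv")
            summary["n_fst_outliers"] = len(outl)

            stage = "intersect"
            kept, contained = intersect_outliers_windows(top, outl)
            regions = merge_windows(kept)
            genes_df = genes if genes is not None else pd.DataFrame(
                columns=["gene_id", "chrom", "start", "end", "strand", "biotype"]
            )
            report = genes_in_candidates(regions, contained, genes_df)
            _write(report, out / "adaptive_report.tsv")
            summary["n_candidate_regions"] = len(regions)
        else:
            log.info("window-scan stages skipped: no trio configured")

        # ---------------------------------------------------------- pi
        stage = "pi"
        pi_rows = []
        for pop in pops:
            _, mean_pi = windowed_pi(gm, pm, pop, window_bp=config.pi_window_bp)
            pi_rows.append({"population": pop, "mean_pi": mean_pi})
        pi_df = pd.DataFrame(pi_rows)
        _write(pi_df, out / "pi.tsv")
        summary["mean_pi"] = dict(zip(pi_df["population"], pi_df["mean_pi"]))

        # ---------------------------------------------- topology weighting
        groups = [config.outgroup] + pops
        if len(groups) >= 4 and gm.n_samples >= len(groups):
            stage = "topo_weights"
            topos = enumerate_topologies(groups)
            group_of = dict(pm.assignments)
            rows = []
            n_sites = gm.n_sites
            step = config.tree_window_snps
            for start in range(0, n_sites - step + 1, step):
                sub = gm.take_sites(np.arange(start, start + step))
                newick = nj_window_tree(sub)
                row = weight_tree(
                    newick, group_of, topos,
                    seed=stage_seed(config.seed, f"topo_{start}"),
                )
                rows.append(
                    {
                        "window_start_snp": start,
                        **{
                            t.newick: w
                            for t, w in zip(topos, row.weights)
                        },
                    }
                )
            tw = pd.DataFrame(rows)
            _write(tw, out / "topology_weights.tsv")
            summary["n_topologies"] = len(topos)

        stage = "finish"
        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
        with open(out / "provenance.json", "w") as fh:
            json.dump(
                {"introscan_version": __version__, "config": dataclasses.asdict(config)},
                fh, indent=2, sort_keys=True,
            )
        return summary
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc


def _top_parents(table: pd.DataFrame, hybrid: str) -> tuple[str, str]:
    rows = table[table["Hybrid"] == hybrid]
    if not len(rows):
        raise ValueError(f"no hybrid-test arrangement with {hybrid!r} as hybrid")
    best = rows.sort_values(["p", "Z"], ascending=[True, False]).iloc[0]
    return str(best["P1"]), str(best["P2"])
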