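"""End-to-end orchestration: simulate/load -> QC -> phase -> frequencies ->
statistics -> distances/trees/PCA -> report bundle.

Every stage is a pure function of (inputs, config, seed); the run manifest
(config hash, seed, package and library versions) suffices to reproduce a
run bit-for-bit.  All outputs are plain TSV/JSON/Newick/PHYLIP files so
stages can be re-run standalone or mixed with external tools.
"""

from __future__ import annotations

import hashlib
import json
import sys
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import io as mio
from .panel import load_panel, summarize_panel, prune_loci
from .phasing import phase_table
from .qc import QCThresholds, apply_qc, dropout_screen, read_support_summary
from .relationships import (distance_matrix, export_structure_format,
                            pca_populations)
from .simulate import (CoverageModel, SimulationConfig, simulate_coverage,
                       simulate_frequencies, simulate_genotypes)
from .stats import (FrequencyTable, allele_census, allele_frequencies,
                    ae_table, informativeness_table, most_common_genotype,
                    random_match_probability, regional_ae_ranking)
from .trees import explore_topologies, neighbor_joining, ols_branch_lengths, \
    write_phylip


@dataclass
class PipelineConfig:
    """Run configuration; any field may be overridden from the CLI."""

    # inputs: either paths or a simulation
    genotypes: str | None = None       # phased genotype TSV
    unphased: str | None = None        # unphased genotype TSV (EM phased)
    coverage: str | None = None        # coverage TSV (enables QC)
    simulate: dict | None = None       # SimulationConfig overrides
    # stage settings
    qc_enabled: bool = True
    qc: dict = field(default_factory=dict)            # QCThresholds overrides
    em_tol: float = 1e-8
    em_max_iter: int = 1000
    census_common: float = 0.05
    census_low: float = 0.02
    ranking_k: int = 20
    tree_search_radius: int = 1
    in_threshold: float = 0.25
    seed: int = 0
    out_dir: str = "microhap_run"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def config_hash(self) -> str:
        canon = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _stage_seeds(seed: int) -> dict[str, int]:
    """Deterministic per-stage child seeds from the global seed."""
    children = np.random.SeedSequence(seed).spawn(3)
    names = ["frequencies", "genotypes", "coverage"]
    return {name: int(c.generate_state(1)[0] % (2 ** 31))
            for name, c in zip(names, children)}


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns a manifest dict (also written to disk).

    Any stage failure aborts with the stage named; outputs of completed
    stages are left in place.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    manifest: dict = {
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stage_seeds": seeds,
        "versions": {
            "microhap": __version__,
            "python": sys.version.split()[0],
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "stages": [],
        "warnings": [],
    }
    stage = "inputs"
    try:
        # -- inputs / simulation ------------------------------------------
        truth = None
        if config.genotypes:
            genotypes = mio.read_genotypes(config.genotypes)
            coverage = (mio.read_coverage(config.coverage)
                        if config.coverage else None)
        elif config.unphased:
            stage = "phase"
            unphased = mio.read_unphased_genotypes(config.unphased)
            genotypes, em_summary = phase_table(
                unphased, tol=config.em_tol, max_iter=config.em_max_iter)
            em_summary.to_csv(out / "em_summary.tsv", sep="\t", index=False)
            coverage = (mio.read_coverage(config.coverage)
                        if config.coverage else None)
        else:
            stage = "simulate"
            sim_kwargs = dict(config.simulate or {})
            cov_kwargs = sim_kwargs.pop("coverage_model", None)
            if cov_kwargs:
                sim_kwargs["coverage_model"] = CoverageModel(**cov_kwargs)
            sim = SimulationConfig(seed=seeds["frequencies"], **sim_kwargs)
            freqset = simulate_frequencies(sim)
            genotypes = simulate_genotypes(freqset, sim.sample_sizes,
                                           seeds["genotypes"])
            coverage, truth = simulate_coverage(
                genotypes, sim.coverage_model, seeds["coverage"])
            mio.write_genotypes(genotypes, out / "genotypes.tsv",
                                "stage: simulate")
            mio.write_coverage(coverage, out / "coverage.tsv",
                               "stage: simulate")
            truth.to_csv(out / "coverage_truth.tsv", sep="\t", index=False)
            FrequencyTable.from_frequency_set(freqset).to_tsv(
                out / "true_frequencies.tsv", "stage: simulate (truth)")
        manifest["stages"].append(stage)

        # -- QC ------------------------------------------------------------
        if config.qc_enabled and coverage is not None:
            stage = "qc"
            thresholds = QCThresholds(**config.qc)
            genotypes, report = apply_qc(coverage, genotypes, thresholds)
            report.removed_genotypes = []
            genotypes, removed = dropout_screen(genotypes)
            report.removed_genotypes = removed
            report.to_json(out / "qc_report.json")
            read_support_summary(coverage).to_csv(
                out / "read_support.tsv", sep="\t", index=False)
            manifest["stages"].append(stage)
        else:
            genotypes, removed = dropout_screen(genotypes)
            manifest["stages"].append("dropout_screen")

        # -- frequencies and statistics -----------------------------------
        stage = "frequencies"
        freqs = allele_frequencies(genotypes)
        freqs.to_tsv(out / "frequencies.tsv", "stage: frequencies")
        manifest["stages"].append(stage)

        stage = "statistics"
        ae = ae_table(freqs)
        ae.round(2).to_csv(out / "ae_by_population.tsv", sep="\t")
        in_series = informativeness_table(freqs)
        locus_table = pd.DataFrame({
            "avg_ae": ae.mean(axis=0).round(2),
            "rosenberg_in": in_series.round(3),
        })
        locus_table.to_csv(out / "locus_statistics.tsv", sep="\t",
                           index_label="locus")
        pops = freqs.populations
        ident = pd.DataFrame({
            "population": pops,
            "log10_rmp": [random_match_probability(freqs, p) for p in pops],
            "log10_most_common_genotype": [
                most_common_genotype(freqs, p) for p in pops],
        })
        ident.to_csv(out / "individualization.tsv", sep="\t", index=False)
        regions = {p: p.split("P")[0] if "P" in p else p for p in pops}
        ranking = regional_ae_ranking(ae, regions, k=config.ranking_k)
        (out / "regional_ranking.json").write_text(json.dumps({
            "per_region": ranking["per_region"],
            "union": ranking["union"],
            "intersection": ranking["intersection"],
        }, indent=2) + "\n")
        census = allele_census(freqs)
        (out / "allele_census.json").write_text(
            json.dumps(asdict(census), indent=2) + "\n")
        manifest["stages"].append(stage)

        # -- distances, trees, PCA ----------------------------------------
        if len(pops) >= 3:
            stage = "distances"
            dm = distance_matrix(freqs)
            write_phylip(dm, out / "tau_distances.phy")
            manifest["stages"].append(stage)

            stage = "trees"
            nj = neighbor_joining(dm)
            nj.write_newick(out / "nj_tree.nwk")
            search = explore_topologies(nj, dm,
                                        radius=config.tree_search_radius)
            search.best.tree.write_newick(out / "best_tree.nwk")
            best_nonneg = search.best_without_negative_internal
            tree_summary = {
                "n_evaluated": search.n_evaluated,
                "n_no_negative_internal": search.n_no_negative_internal,
                "best_residual_ss": search.best.residual_ss,
                "best_negative_internal": search.best.n_negative_internal,
            }
            if best_nonneg is not None:
                best_nonneg.tree.write_newick(
                    out / "best_tree_no_negative.nwk")
                tree_summary["best_nonnegative_residual_ss"] = \
                    best_nonneg.residual_ss
            (out / "tree_search.json").write_text(
                json.dumps(tree_summary, indent=2) + "\n")
            manifest["stages"].append(stage)

            stage = "pca"
            coords, evr = pca_populations(freqs)
            coords.round(10).to_csv(out / "pca_coordinates.tsv", sep="\t",
                                    index_label="population")
            np.savetxt(out / "pca_explained_variance.tsv", evr,
                       header="explained_variance_ratio", comments="# ")
            manifest["stages"].append(stage)

        stage = "export"
        export_structure_format(genotypes, out / "structure_input.txt")
        manifest["stages"].append(stage)
    except Exception as exc:
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=2, default=str) + "\n")
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, default=str) + "\n")
    return manifest


def panel_summary_report(panel_path: str | None = None,
                         in_threshold: float = 0.25) -> dict:
    """Summary of a panel table (the packaged one by default)."""
    panel = load_panel(panel_path)
    summary = summarize_panel(panel, in_threshold)
    pruned = prune_loci(panel, in_threshold)
    return {
        "n_loci": summary.n_loci,
        "total_snp_count": summary.total_snp_count,
        "in_threshold": in_threshold,
        "n_below_in_threshold": summary.n_below_in_threshold,
        "n_retained_after_pruning": len(pruned),
        "max_avg_ae": {"locus": summary.max_avg_ae[0],
                       "value": summary.max_avg_ae[1]},
        "min_avg_ae": {"locus": summary.min_avg_ae[0],
                       "value": summary.min_avg_ae[1]},
        "max_in": {"locus": summary.max_in[0], "value": summary.max_in[1]},
    }
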