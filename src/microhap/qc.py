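"""Three-level sequencing QC and the homozygote-dropout screen.

Amplicon sequencing of a multiplexed marker panel is monitored at three
levels: total reads per sample (multiplex-PCR failure), amplicon-coverage
uniformity within a sample (partial amplification failure), and the fraction
of bases covered at >= 100x (base-level adequacy).  A sample is removed only
when it fails all three levels; samples flagged at one or two levels are
retained but reported.  All thresholds are strict ``<`` comparisons, so
boundary values pass.

The dropout screen targets a specific artifact of allele dropout: an allele
whose only occurrences in the whole dataset are the two copies of a single
homozygous genotype in one individual is likely a heterozygote whose second
allele dropped out; that genotype is set to missing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .io import MISSING, coverage_locus_columns

__all__ = [
    "QCThresholds",
    "QCReport",
    "QCFilter",
    "qc_sample_coverage",
    "qc_amplicon_uniformity",
    "qc_base_coverage",
    "apply_qc",
    "dropout_screen",
    "read_support_summary",
]


@dataclass(frozen=True)
class QCThresholds:
    min_reads: int = 150_000      # total reads per sample
    rel_floor: float = 0.2        # amplicon counts as covered above this x mean
    k_sd: float = 2.0             # SDs below the mean amplicon-uniformity count
    min_frac: float = 0.75        # fraction of bases at >= depth
    depth: int = 100
    removal_policy: str = "all"   # remove iff all three flags, or "any"


@dataclass
class QCReport:
    flags: pd.DataFrame                 # per sample: three boolean columns
    removed_samples: list[str]
    flagged_samples: list[str]          # flagged at >=1 level but retained
    removed_genotypes: list[tuple[str, str]] = field(default_factory=list)
    mean_reads_per_sample: float = float("nan")
    thresholds: QCThresholds = field(default_factory=QCThresholds)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "thresholds": asdict(self.thresholds),
            "mean_reads_per_sample": self.mean_reads_per_sample,
            "flags": {
                row["sample_id"]: {
                    k: bool(row[k]) for k in
                    ("low_sample_coverage", "low_amplicon_uniformity",
                     "low_base_coverage")}
                for _, row in self.flags.reset_index().iterrows()},
            "removed_samples": self.removed_samples,
            "flagged_samples": self.flagged_samples,
            "removed_genotypes": [list(t) for t in self.removed_genotypes],
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def qc_sample_coverage(coverage: pd.DataFrame,
                       min_reads: int = 150_000) -> pd.Series:
    """Flag samples with total reads strictly below *min_reads*."""
    if coverage.empty:
        raise ValueError("empty coverage table")
    return pd.Series(coverage["total_reads"].to_numpy() < min_reads,
                     index=coverage["sample_id"],
                     name="low_sample_coverage")


def qc_amplicon_uniformity(coverage: pd.DataFrame, rel_floor: float = 0.2,
                           k_sd: float = 2.0) -> pd.Series:
    """Flag samples whose count of adequately covered amplicons is more than
    *k_sd* population SDs below the across-sample mean of that count.

    An amplicon counts as adequately covered when its reads exceed
    *rel_floor* times the sample's mean amplicon coverage.
    """
    if len(coverage) < 3:
        raise ValueError("amplicon-uniformity QC needs >= 3 samples "
                         "(across-sample SD undefined otherwise)")
    counts = coverage[coverage_locus_columns(coverage)].to_numpy(float)
    mean_per_sample = counts.mean(axis=1, keepdims=True)
    u = (counts > rel_floor * mean_per_sample).sum(axis=1)
    cutoff = u.mean() - k_sd * u.std()  # population SD
    return pd.Series(u < cutoff, index=coverage["sample_id"],
                     name="low_amplicon_uniformity")


def qc_base_coverage(coverage: pd.DataFrame,
                     min_frac: float = 0.75, depth: int = 100) -> pd.Series:
    """Flag samples with under *min_frac* of bases at >= *depth* reads."""
    frac = coverage["frac_bases_100x"].to_numpy(float)
    if ((frac < 0) | (frac > 1)).any():
        raise ValueError("frac_bases_100x outside [0, 1]")
    return pd.Series(frac < min_frac, index=coverage["sample_id"],
                     name="low_base_coverage")


class QCFilter(BaseEstimator):
    """Coverage-based sample QC as a fit/transform step.

    ``fit`` computes the three per-sample flags from a coverage table;
    ``transform`` drops removed samples from a genotype table.  Fitted
    attributes: ``flags_``, ``removed_samples_``, ``flagged_samples_``,
    ``report_``.
    """

    def __init__(self, min_reads: int = 150_000, rel_floor: float = 0.2,
                 k_sd: float = 2.0, min_frac: float = 0.75, depth: int = 100,
                 removal_policy: str = "all"):
        self.min_reads = min_reads
        self.rel_floor = rel_floor
        self.k_sd = k_sd
        self.min_frac = min_frac
        self.depth = depth
        self.removal_policy = removal_policy

    def fit(self, X: pd.DataFrame, y=None) -> "QCFilter":
        if self.removal_policy not in ("all", "any"):
            raise ValueError("removal_policy must be 'all' or 'any'")
        coverage = X
        flags = pd.concat([
            qc_sample_coverage(coverage, self.min_reads),
            qc_amplicon_uniformity(coverage, self.rel_floor, self.k_sd),
            qc_base_coverage(coverage, self.min_frac, self.depth),
        ], axis=1)
        combine = flags.all(axis=1) if self.removal_policy == "all" \
            else flags.any(axis=1)
        self.flags_ = flags
        self.removed_samples_ = sorted(flags.index[combine])
        self.flagged_samples_ = sorted(
            flags.index[flags.any(axis=1) & ~combine])
        self.report_ = QCReport(
            flags=flags,
            removed_samples=self.removed_samples_,
            flagged_samples=self.flagged_samples_,
            mean_reads_per_sample=float(coverage["total_reads"].mean()),
            thresholds=QCThresholds(self.min_reads, self.rel_floor, self.k_sd,
                                    self.min_frac, self.depth,
                                    self.removal_policy),
        )
        return self

    def transform(self, genotypes: pd.DataFrame) -> pd.DataFrame:
        removed = set(self.removed_samples_)
        return genotypes[~genotypes["sample"].isin(removed)].reset_index(
            drop=True)


def apply_qc(coverage: pd.DataFrame, genotypes: pd.DataFrame,
             thresholds: QCThresholds | None = None,
             ) -> tuple[pd.DataFrame, QCReport]:
    """Run all three QC levels and remove failing samples from *genotypes*."""
    t = thresholds or QCThresholds()
    qf = QCFilter(t.min_reads, t.rel_floor, t.k_sd, t.min_frac, t.depth,
                  t.removal_policy).fit(coverage)
    return qf.transform(genotypes), qf.report_


def dropout_screen(genotypes: pd.DataFrame
                   ) -> tuple[pd.DataFrame, list[tuple[str, str]]]:
    """Remove genotypes consistent with allele dropout.

    A genotype is removed (set to missing) when it is homozygous for an
    allele whose two copies in that one individual are the allele's only
    occurrences in the whole dataset.
    """
    out = genotypes.copy()
    called = out[(out["allele1"] != MISSING) & out["allele1"].notna()]
    melted = pd.concat([
        called[["sample", "locus", "allele1"]].rename(
            columns={"allele1": "allele"}),
        called[["sample", "locus", "allele2"]].rename(
            columns={"allele2": "allele"}),
    ])
    per_allele = melted.groupby(["locus", "allele"]).agg(
        copies=("sample", "size"), n_samples=("sample", "nunique"))
    # two copies in one sample <=> a single homozygote and nothing else
    singleton = per_allele[(per_allele["copies"] == 2)
                           & (per_allele["n_samples"] == 1)].index
    hom = called[called["allele1"] == called["allele2"]]
    keys = pd.MultiIndex.from_frame(hom[["locus", "allele1"]])
    hits = hom[keys.isin(singleton)]
    removed = sorted(zip(hits["sample"], hits["locus"]))
    if removed:
        mask = pd.MultiIndex.from_frame(out[["sample", "locus"]]).isin(
            removed)
        out.loc[mask, ["allele1", "allele2"]] = MISSING
    return out, removed


def read_support_summary(coverage: pd.DataFrame,
                         min_reads_per_allele: float = 100.0) -> pd.DataFrame:
    """Mean reads per locus and per allele (half the locus mean, diploid),
    with a flag for loci averaging below *min_reads_per_allele*."""
    if coverage.empty:
        raise ValueError("empty coverage table")
    loci = coverage_locus_columns(coverage)
    if not loci:
        raise ValueError("coverage table has no amplicon columns")
    mean_reads = coverage[loci].mean(axis=0)
    summary = pd.DataFrame({
        "locus": loci,
        "mean_reads": mean_reads.to_numpy(float),
        "mean_reads_per_allele": mean_reads.to_numpy(float) / 2.0,
    })
    summary["below_min"] = (
        summary["mean_reads_per_allele"] < min_reads_per_allele)
    return summary
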