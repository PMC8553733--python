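"""Within-population and regional marker statistics.

Core quantities for evaluating a multi-allelic forensic marker panel:

* effective number of alleles ``A_e = 1 / sum(p_i^2)`` — the inverse of
  expected homozygosity, i.e. the number of equally frequent alleles with
  the same heterozygosity;
* Rosenberg informativeness for assignment
  ``I_n = sum_j ( -pbar_j ln pbar_j + (1/K) sum_i p_ij ln p_ij )`` over K
  populations (natural log, ``0 ln 0 := 0``);
* random match probability (RMP): per locus the sum of squared
  Hardy-Weinberg genotype frequencies, multiplied over loci; reported in
  log10 because panel-wide values reach the 1e-115 scale;
* most-common-genotype frequency: product over loci of the largest HWE
  genotype frequency;
* the allele census, regional A_e rankings, and the minimum-contributor
  rule for mixtures (``ceil(k/2)`` for ``k`` distinct alleles at a locus).

RMP and the most-common genotype are computed from HWE expectations rather
than observed genotype counts: per-population samples are small enough that
observed genotype frequencies are unstable, and the product rule is an HWE
argument in the first place.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import MISSING

__all__ = [
    "FrequencyTable",
    "allele_frequencies",
    "effective_alleles",
    "informativeness",
    "random_match_probability",
    "most_common_genotype",
    "ae_table",
    "informativeness_table",
    "regional_ae_ranking",
    "AlleleCensus",
    "allele_census",
    "min_contributors",
]


class FrequencyTable:
    """Per-(population, locus) allele-frequency vectors with sample sizes.

    Thin wrapper over a long-format DataFrame (population, locus, allele,
    frequency, n_copies) providing aligned per-locus matrices across
    populations (absent alleles fill with 0).
    """

    def __init__(self, frame: pd.DataFrame):
        required = {"population", "locus", "allele", "frequency", "n_copies"}
        missing = required - set(frame.columns)
        if missing:
            raise ValueError(f"frequency table missing columns "
                             f"{sorted(missing)}")
        self.frame = frame.reset_index(drop=True)
        sums = frame.groupby(["population", "locus"])["frequency"].sum()
        bad = sums[(sums - 1.0).abs() > 1e-9]
        if not bad.empty:
            raise ValueError(f"frequencies do not sum to 1 for cells "
                             f"{list(bad.index[:5])}")

    @property
    def populations(self) -> list[str]:
        return sorted(self.frame["population"].unique())

    @property
    def loci(self) -> list[str]:
        return sorted(self.frame["locus"].unique())

    def vector(self, population: str, locus: str) -> pd.Series:
        sub = self.frame[(self.frame["population"] == population)
                         & (self.frame["locus"] == locus)]
        if sub.empty:
            raise KeyError((population, locus))
        return pd.Series(sub["frequency"].to_numpy(),
                         index=sub["allele"].to_list(), name="frequency")

    def n_copies(self, population: str, locus: str) -> int:
        sub = self.frame[(self.frame["population"] == population)
                         & (self.frame["locus"] == locus)]
        if sub.empty:
            raise KeyError((population, locus))
        return int(sub["n_copies"].iloc[0])

    def has_cell(self, population: str, locus: str) -> bool:
        return not self.frame[
            (self.frame["population"] == population)
            & (self.frame["locus"] == locus)].empty

    def matrix(self, locus: str,
               populations: list[str] | None = None) -> pd.DataFrame:
        """Populations x alleles frequency matrix for one locus."""
        sub = self.frame[self.frame["locus"] == locus]
        if sub.empty:
            raise KeyError(locus)
        mat = sub.pivot_table(index="population", columns="allele",
                              values="frequency", fill_value=0.0,
                              aggfunc="sum")
        if populations is not None:
            mat = mat.reindex([p for p in populations if p in mat.index])
        return mat

    def to_tsv(self, path, header_comment: str | None = None) -> None:
        from .io import _write_tsv
        _write_tsv(self.frame, path, header_comment)

    @classmethod
    def from_tsv(cls, path) -> "FrequencyTable":
        frame = pd.read_csv(path, sep="\t", comment="#",
                            dtype={"population": str, "locus": str,
                                   "allele": str})
        return cls(frame)

    @classmethod
    def from_frequency_set(cls, freqs) -> "FrequencyTable":
        """Build from a simulation :class:`~microhap.simulate.FrequencySet`
        (generating truth; n_copies set to 0)."""
        frame = freqs.to_frame()
        frame["n_copies"] = 0
        return cls(frame)


def allele_frequencies(genotypes: pd.DataFrame) -> FrequencyTable:
    """Count allele frequencies over 2n gene copies per population/locus.

    Missing genotypes are excluded from the denominator; a cell whose
    genotypes are all missing is absent from the table (with a warning).
    """
    rows = []
    for (pop, locus), grp in genotypes.groupby(["population", "locus"],
                                               sort=True):
        called = grp[(grp["allele1"] != MISSING) & grp["allele1"].notna()]
        if called.empty:
            warnings.warn(f"({pop}, {locus}): no called genotypes; cell "
                          "absent", stacklevel=2)
            continue
        alleles = pd.concat([called["allele1"], called["allele2"]])
        counts = alleles.value_counts().sort_index()
        n = int(counts.sum())
        for allele, c in counts.items():
            rows.append((pop, locus, allele, c / n, n))
    return FrequencyTable(pd.DataFrame(
        rows, columns=["population", "locus", "allele", "frequency",
                       "n_copies"]))


def effective_alleles(p) -> float:
    """``A_e = 1 / sum(p_i^2)``; equals k for k equally frequent alleles."""
    p = np.asarray(p, dtype=float)
    if abs(p.sum() - 1.0) > 1e-6:
        raise ValueError("frequencies must sum to 1")
    return float(1.0 / np.square(p).sum())


def informativeness(freq_matrix) -> float:
    """Rosenberg informativeness for assignment over K >= 2 populations.

    *freq_matrix* is K x N (rows sum to 1, shared allele universe).  Natural
    log; bounded by ``0 <= I_n <= ln K`` with 0 iff all rows identical.
    """
    m = np.asarray(freq_matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] < 2:
        raise ValueError("need a K x N matrix with K >= 2 populations")
    if np.abs(m.sum(axis=1) - 1.0).max() > 1e-6:
        raise ValueError("each population's frequencies must sum to 1")
    k = m.shape[0]
    pbar = m.mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        term_mean = np.where(pbar > 0, -pbar * np.log(pbar), 0.0)
        term_pops = np.where(m > 0, m * np.log(m), 0.0)
    return float(term_mean.sum() + term_pops.sum() / k)


def _hwe_genotype_frequencies(p: np.ndarray) -> np.ndarray:
    """All HWE genotype frequencies (p_i^2 and 2 p_i p_j, i < j)."""
    outer = np.outer(p, p)
    hom = np.diag(outer)
    het = 2.0 * outer[np.triu_indices(len(p), k=1)]
    return np.concatenate([hom, het])


def random_match_probability(freqs: FrequencyTable, population: str,
                             loci: list[str] | None = None) -> float:
    """log10 RMP over *loci* (all by default) for one population.

    Loci with no data in the population are skipped with a warning.
    """
    return _genotype_product(freqs, population, loci,
                             lambda g: np.square(g).sum())


def most_common_genotype(freqs: FrequencyTable, population: str,
                         loci: list[str] | None = None) -> float:
    """log10 frequency of the most common multi-locus HWE genotype."""
    return _genotype_product(freqs, population, loci, np.max)


def _genotype_product(freqs: FrequencyTable, population: str,
                      loci: list[str] | None, reducer) -> float:
    loci = freqs.loci if loci is None else loci
    total = 0.0
    for locus in loci:
        if not freqs.has_cell(population, locus):
            warnings.warn(f"({population}, {locus}): no data; locus skipped "
                          "in product", stacklevel=3)
            continue
        p = freqs.vector(population, locus).to_numpy()
        total += math.log10(reducer(_hwe_genotype_frequencies(p)))
    return total


def ae_table(freqs: FrequencyTable) -> pd.DataFrame:
    """Populations x loci matrix of per-cell A_e values."""
    records = {}
    for (pop, locus), grp in freqs.frame.groupby(["population", "locus"]):
        records[(pop, locus)] = effective_alleles(
            grp["frequency"].to_numpy())
    ser = pd.Series(records)
    return ser.unstack()


def informativeness_table(freqs: FrequencyTable,
                          populations: list[str] | None = None) -> pd.Series:
    """Per-locus I_n across the given populations (all by default)."""
    pops = populations or freqs.populations
    values = {}
    for locus in freqs.loci:
        mat = freqs.matrix(locus, pops)
        if len(mat) >= 2:
            values[locus] = informativeness(mat.to_numpy())
    return pd.Series(values, name="informativeness")


def regional_ae_ranking(ae: pd.DataFrame, regions: dict[str, str],
                        k: int = 20) -> dict:
    """Top-k loci by mean A_e within each region, plus the cross-region
    union and intersection of those lists.

    *ae* is the populations x loci matrix from :func:`ae_table`; *regions*
    maps population -> region label.
    """
    region_series = pd.Series({p: regions[p] for p in ae.index})
    per_region = ae.groupby(region_series).mean()
    rankings = {}
    for region, row in per_region.iterrows():
        ranked = row.sort_values(ascending=False, kind="stable")
        rankings[region] = list(ranked.index[:k])
    lists = list(rankings.values())
    union = sorted(set().union(*lists)) if lists else []
    inter = sorted(set(lists[0]).intersection(*lists[1:])) if lists else []
    return {"per_region": rankings,
            "regional_mean_ae": per_region,
            "union": union,
            "intersection": inter}


@dataclass(frozen=True)
class AlleleCensus:
    total: int            # distinct alleles dataset-wide
    common_ge_5pct: int   # max per-population frequency >= 0.05
    over_2pct: int        # max per-population frequency > 0.02 (strict)
    copies_le_2: int      # dataset-wide copy count <= 2


def allele_census(freqs: FrequencyTable) -> AlleleCensus:
    """Census of distinct alleles by their frequency class.

    Copy counts are reconstructed from frequency x 2n per cell, so the
    table must come from genotype counting (``n_copies > 0``).
    """
    frame = freqs.frame
    copies = (frame["frequency"] * frame["n_copies"]).round().astype(int)
    per_allele = frame.assign(copies=copies).groupby(["locus", "allele"])
    max_freq = per_allele["frequency"].max()
    total_copies = per_allele["copies"].sum()
    return AlleleCensus(
        total=len(max_freq),
        common_ge_5pct=int((max_freq >= 0.05).sum()),
        over_2pct=int((max_freq > 0.02).sum()),
        copies_le_2=int((total_copies <= 2).sum()),
    )


def min_contributors(allele_counts) -> tuple[dict, int]:
    """Minimum mixture contributors: per locus ``ceil(k/2)`` for ``k``
    distinct alleles observed; the overall minimum is the max over loci.

    *allele_counts* maps locus -> number of distinct alleles seen (an int is
    accepted for a single locus).
    """
    if isinstance(allele_counts, int):
        allele_counts = {"locus": allele_counts}
    per_locus = {}
    for locus, k in allele_counts.items():
        if k < 1:
            raise ValueError(f"{locus}: allele count must be >= 1")
        per_locus[locus] = math.ceil(k / 2)
    return per_locus, max(per_locus.values())
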