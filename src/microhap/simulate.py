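"""Synthetic populations, genotypes, and read-coverage tables.

The generator emulates the statistical structure the downstream analyses
assume: ~79 populations in 6 biogeographic regions, multi-allelic loci
(3-30+ alleles per locus), a more diverse "ancestral" region with a clinal
decline of the effective number of alleles in regions that accumulated more
drift, Hardy-Weinberg genotypes within populations, and an amplicon
read-coverage model with occasional sample/amplicon/base-coverage failures.

Frequencies evolve by pure Wright-Fisher drift (iterated multinomial
resampling of ``2 N_e`` gene copies), so the expected drift-time distance
between two populations separated for ``t`` generations is ``t / (2 N_e)`` —
the calibration the tau distance is tested against.  A Balding-Nichols
Dirichlet sampler is available as a cheaper alternative mode.

Determinism: one global seed expands into per-stage child seeds through
``numpy.random.SeedSequence(seed).spawn``, in the documented order
(ancestral frequencies, region drift, population drift); identical
config + seed gives bit-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import GENOTYPE_COLUMNS

__all__ = [
    "CoverageModel",
    "SimulationConfig",
    "FrequencySet",
    "drift_frequencies",
    "simulate_frequencies",
    "simulate_genotypes",
    "simulate_coverage",
]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class CoverageModel:
    """Negative-binomial read-coverage model with injected failure modes.

    Defaults reflect the sequencing depths the panel assay was designed for:
    ~700k reads per sample on a 90-plex, near-complete per-base coverage.
    """

    mean_reads: float = 705_536.0
    dispersion: float = 8.0              # NB shape; CV ~ 1/sqrt(dispersion)
    failed_mean_reads: float = 50_000.0  # mean for samples failing multiplex PCR
    amplicon_concentration: float = 50.0 # Dirichlet conc. per amplicon share
    base_frac_beta: tuple[float, float] = (60.0, 2.0)   # clean samples
    failed_base_frac_beta: tuple[float, float] = (8.0, 4.0)
    sample_failure_rate: float = 0.02    # ~8/384 flagged for low reads
    amplicon_failure_rate: float = 0.01  # ~4/384 poor uniformity
    base_failure_rate: float = 0.013     # ~5/384 low base coverage


@dataclass(frozen=True)
class SimulationConfig:
    """World definition for the synthetic dataset.

    Defaults state the world the analyses expect: 6 regions holding
    16/15/24/14/7/3 populations (79 total), 90 multi-allelic loci, and a
    clinal increase of cumulative drift away from the ancestral region
    (region drift times in ``t/(2 N_e)`` units from 0.02 to 0.20, spanning
    the range of human continental differentiation), plus 0.02 of
    population-private drift.
    """

    n_regions: int = 6
    populations_per_region: tuple[int, ...] = (16, 15, 24, 14, 7, 3)
    n_loci: int = 90
    alleles_per_locus: tuple[int, int] = (3, 30)
    dirichlet_concentration: float = 0.5
    region_drift: tuple[float, ...] | None = None  # t/(2Ne) per region
    population_drift: float = 0.02                 # extra t/(2Ne) per population
    effective_size: int = 500
    sample_sizes: int | tuple[int, ...] = 50       # diploid individuals per pop
    seed: int = 0
    drift_mode: str = "wright_fisher"              # or "balding_nichols"
    coverage_model: CoverageModel = field(default_factory=CoverageModel)

    def __post_init__(self):
        if len(self.populations_per_region) != self.n_regions:
            raise ValueError("populations_per_region length != n_regions")
        if self.n_loci <= 0 or self.effective_size <= 0:
            raise ValueError("counts must be positive")
        lo, hi = self.alleles_per_locus
        if not (2 <= lo <= hi):
            raise ValueError("alleles_per_locus range invalid")
        if self.drift_mode not in ("wright_fisher", "balding_nichols"):
            raise ValueError(f"unknown drift_mode {self.drift_mode!r}")

    def resolved_region_drift(self) -> tuple[float, ...]:
        if self.region_drift is not None:
            if len(self.region_drift) != self.n_regions:
                raise ValueError("region_drift length != n_regions")
            return tuple(self.region_drift)
        if self.n_regions == 1:
            return (0.02,)
        return tuple(np.linspace(0.02, 0.20, self.n_regions))

    @property
    def populations(self) -> list[str]:
        return [f"R{r + 1}P{i + 1:02d}"
                for r in range(self.n_regions)
                for i in range(self.populations_per_region[r])]

    def region_of(self, population: str) -> str:
        return population.split("P")[0]


class FrequencySet:
    """Per-(population, locus) allele-frequency vectors on a shared allele
    universe per locus.

    Alleles are SNP-state strings; alleles lost to drift keep their column
    (frequency 0) so cross-population comparisons stay aligned.
    """

    def __init__(self, alleles: dict[str, list[str]],
                 freqs: dict[tuple[str, str], np.ndarray],
                 population_region: dict[str, str]):
        self.alleles = alleles
        self._freqs = freqs
        self.population_region = population_region
        self.populations = sorted({p for p, _ in freqs})
        self.loci = list(alleles)
        for (pop, locus), p in freqs.items():
            if abs(p.sum() - 1.0) > 1e-12:
                raise ValueError(f"frequencies for ({pop}, {locus}) sum to "
                                 f"{p.sum()!r}, not 1")
            if (p < 0).any():
                raise ValueError(f"negative frequency in ({pop}, {locus})")

    def freq(self, population: str, locus: str) -> np.ndarray:
        return self._freqs[(population, locus)]

    def items(self):
        return self._freqs.items()

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (pop, locus), p in self._freqs.items():
            for allele, f in zip(self.alleles[locus], p):
                rows.append((pop, locus, allele, f))
        return pd.DataFrame(rows,
                            columns=["population", "locus", "allele",
                                     "frequency"])


def drift_frequencies(p: np.ndarray, n_e: int, generations: int,
                      rng: np.random.Generator | int) -> np.ndarray:
    """Wright-Fisher drift: *generations* rounds of multinomial resampling of
    ``2 n_e`` gene copies.  Fixed alleles stay fixed; output sums to 1."""
    if n_e <= 0:
        raise ValueError("n_e must be positive")
    p = np.asarray(p, dtype=float)
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("input frequencies must sum to 1")
    rng = np.random.default_rng(rng) if not isinstance(
        rng, np.random.Generator) else rng
    copies = 2 * n_e
    for _ in range(generations):
        p = rng.multinomial(copies, p / p.sum()) / copies
    return p


def _balding_nichols(p: np.ndarray, fst: float,
                     rng: np.random.Generator) -> np.ndarray:
    """Dirichlet drift stand-in with inbreeding coefficient *fst*."""
    if fst <= 0:
        return p.copy()
    scale = (1.0 - fst) / fst
    alpha = np.clip(p * scale, 1e-9, None)
    out = rng.dirichlet(alpha)
    # alleles already lost stay lost
    out[p == 0] = 0.0
    return out / out.sum()


def _drift(p: np.ndarray, tau: float, n_e: int, mode: str,
           rng: np.random.Generator) -> np.ndarray:
    if mode == "wright_fisher":
        return drift_frequencies(p, n_e, int(round(tau * 2 * n_e)), rng)
    fst = 1.0 - (1.0 - 1.0 / (2 * n_e)) ** int(round(tau * 2 * n_e))
    return _balding_nichols(p, fst, rng)


def _random_haplotypes(k: int, rng: np.random.Generator) -> list[str]:
    """k distinct SNP-state strings; length grows with k (>= 2 SNPs)."""
    length = max(2, math.ceil(math.log(k, 4)) + 1)
    codes = rng.choice(4 ** length, size=k, replace=False)
    haps = []
    for c in codes:
        digits = [(c // 4 ** i) % 4 for i in range(length)]
        haps.append("".join(_BASES[d] for d in digits))
    return haps


def simulate_frequencies(config: SimulationConfig) -> FrequencySet:
    """Ancestral Dirichlet frequencies per locus, drifted per region and then
    per population.  Larger cumulative drift lowers the expected effective
    number of alleles, producing the clinal pattern away from the ancestral
    region."""
    ss = np.random.SeedSequence(config.seed)
    rng_anc, rng_region, rng_pop = (np.random.default_rng(s)
                                    for s in ss.spawn(3))
    lo, hi = config.alleles_per_locus
    loci = [f"L{i + 1:03d}" for i in range(config.n_loci)]
    alleles: dict[str, list[str]] = {}
    ancestral: dict[str, np.ndarray] = {}
    for locus in loci:
        k = int(rng_anc.integers(lo, hi + 1))
        alleles[locus] = sorted(_random_haplotypes(k, rng_anc))
        ancestral[locus] = rng_anc.dirichlet(
            np.full(k, config.dirichlet_concentration))

    region_drift = config.resolved_region_drift()
    freqs: dict[tuple[str, str], np.ndarray] = {}
    population_region: dict[str, str] = {}
    for r in range(config.n_regions):
        region_name = f"R{r + 1}"
        regional = {
            locus: _drift(ancestral[locus], region_drift[r],
                          config.effective_size, config.drift_mode,
                          rng_region)
            for locus in loci}
        for i in range(config.populations_per_region[r]):
            pop = f"{region_name}P{i + 1:02d}"
            population_region[pop] = region_name
            for locus in loci:
                freqs[(pop, locus)] = _drift(
                    regional[locus], config.population_drift,
                    config.effective_size, config.drift_mode, rng_pop)
    return FrequencySet(alleles, freqs, population_region)


def simulate_genotypes(freqs: FrequencySet,
                       sample_sizes: int | dict[str, int],
                       seed: int) -> pd.DataFrame:
    """Hardy-Weinberg diploid genotypes: two alleles drawn independently per
    individual per locus.  Output is a phased genotype table."""
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    if isinstance(sample_sizes, int):
        sample_sizes = {pop: sample_sizes for pop in freqs.populations}
    elif isinstance(sample_sizes, (list, tuple)):
        if len(sample_sizes) != len(freqs.populations):
            raise ValueError("sample_sizes length != number of populations")
        sample_sizes = dict(zip(freqs.populations, sample_sizes))
    missing = set(freqs.populations) - set(sample_sizes)
    if missing:
        raise ValueError(f"no sample size for populations {sorted(missing)}")
    rows = []
    for pop in freqs.populations:
        n = sample_sizes[pop]
        samples = [f"{pop}_S{i + 1:03d}" for i in range(n)]
        for locus in freqs.loci:
            p = freqs.freq(pop, locus)
            labels = freqs.alleles[locus]
            draws = rng.choice(len(labels), size=(n, 2), p=p)
            for s, (a, b) in zip(samples, draws):
                rows.append((s, pop, locus, labels[a], labels[b]))
    return pd.DataFrame(rows, columns=GENOTYPE_COLUMNS)


def simulate_coverage(genotypes: pd.DataFrame,
                      model: CoverageModel | None = None,
                      seed: int = 0,
                      ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-sample coverage table plus truth labels for injected failures.

    Returns ``(coverage, truth)``; *truth* has boolean columns
    ``fail_sample`` / ``fail_amplicon`` / ``fail_base`` marking injected
    failures, against which downstream QC flags can be validated.
    """
    model = model or CoverageModel()
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    samples = list(pd.unique(genotypes["sample"]))
    loci = sorted(pd.unique(genotypes["locus"]))
    n_loci = len(loci)
    cov_rows, truth_rows = [], []
    for s in samples:
        fail_sample = rng.random() < model.sample_failure_rate
        fail_amp = rng.random() < model.amplicon_failure_rate
        fail_base = rng.random() < model.base_failure_rate
        mean = model.failed_mean_reads if fail_sample else model.mean_reads
        r = model.dispersion
        total = int(rng.negative_binomial(r, r / (r + mean)))
        shares = rng.dirichlet(np.full(n_loci, model.amplicon_concentration))
        if fail_amp:
            dead = rng.choice(n_loci, size=n_loci // 2, replace=False)
            shares[dead] *= 1e-3
            shares /= shares.sum()
        a, b = (model.failed_base_frac_beta if fail_base
                else model.base_frac_beta)
        frac = float(rng.beta(a, b))
        per_amplicon = np.round(shares * total).astype(int)
        cov_rows.append([s, total, frac, *per_amplicon])
        truth_rows.append([s, fail_sample, fail_amp, fail_base])
    coverage = pd.DataFrame(
        cov_rows, columns=["sample_id", "total_reads", "frac_bases_100x",
                           *loci])
    truth = pd.DataFrame(
        truth_rows, columns=["sample_id", "fail_sample", "fail_amplicon",
                             "fail_base"])
    return coverage, truth
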