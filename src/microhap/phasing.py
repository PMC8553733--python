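"""Haplotype-frequency estimation and phasing for multi-SNP loci.

Each microhaplotype locus spans a handful of SNPs close enough to be read as
one molecule; its "alleles" are the phased SNP-state strings.  When input
genotypes arrive unphased (per-SNP diploid calls), the locus allele
frequencies are estimated with the classic gametic EM algorithm: enumerate
the ordered haplotype pairs compatible with each individual's heterozygous
sites, weight them by their current Hardy-Weinberg probabilities (E-step),
and re-count haplotypes (M-step).  The log-likelihood is non-decreasing and
the fixed point maximizes the multinomial HWE likelihood.  Individuals are
then assigned their maximum-posterior pair.

No recombination/coalescent prior is used (unlike PHASE): loci are short
enough that within-locus recombination is negligible, and sample sizes per
population are small.  Individuals with missing SNP calls at a locus are
excluded from that locus's EM (pairwise deletion) and phased as missing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .io import GENOTYPE_COLUMNS, MISSING

__all__ = [
    "parse_snp_genotypes",
    "enumerate_compatible_pairs",
    "EMHaplotypeFrequencies",
    "em_haplotype_frequencies",
    "phase_genotypes",
    "phase_table",
    "unphase_table",
]

SnpGenotype = tuple[tuple[str, str], ...]


def parse_snp_genotypes(text: str) -> SnpGenotype:
    """Parse ``"A/G;C/C;T/A"`` into per-SNP unordered calls (sorted pairs).

    A bare ``"."`` denotes a fully missing genotype.
    """
    if text == MISSING:
        return ((MISSING, MISSING),)
    calls = []
    for part in text.split(";"):
        a, _, b = part.partition("/")
        if not b:
            raise ValueError(f"bad SNP genotype field {part!r} in {text!r}")
        calls.append(tuple(sorted((a, b))))
    return tuple(calls)


def has_missing(g: SnpGenotype) -> bool:
    return any(MISSING in call for call in g)


def enumerate_compatible_pairs(g: SnpGenotype) -> list[tuple[str, str]]:
    """All unordered haplotype pairs compatible with an unphased genotype.

    With ``h`` heterozygous SNPs there are ``2**(h-1)`` pairs (one when
    ``h <= 1``): the first heterozygous site is pinned to the first
    haplotype, the remaining ``h - 1`` sites vary freely.  Pairs are returned
    in a deterministic order with each pair sorted lexicographically.
    """
    if has_missing(g):
        raise ValueError("cannot enumerate pairs with missing SNP calls")
    het = [i for i, (a, b) in enumerate(g) if a != b]
    base1 = [a for a, _ in g]
    base2 = [b for _, b in g]
    if not het:
        hap = "".join(base1)
        return [(hap, hap)]
    free = het[1:]
    pairs = []
    for mask in range(2 ** len(free)):
        h1, h2 = base1[:], base2[:]
        for bit, i in enumerate(free):
            if (mask >> bit) & 1:
                h1[i], h2[i] = h2[i], h1[i]
        pair = tuple(sorted(("".join(h1), "".join(h2))))
        pairs.append(pair)
    return sorted(set(pairs))


class EMHaplotypeFrequencies(BaseEstimator):
    """Gametic EM estimator of haplotype (microhaplotype-allele) frequencies.

    Parameters
    ----------
    tol : float
        Convergence tolerance on the log-likelihood increase.
    max_iter : int
        Iteration cap; non-convergence is recorded, not raised.
    n_restarts : int
        Extra EM runs from random Dirichlet starts; the best log-likelihood
        wins.  0 keeps only the uniform start over observed-compatible
        haplotypes.
    random_state : int or None
        Seed for the random restarts.

    Fitted attributes: ``haplotypes_`` (sorted labels), ``frequencies_``
    (aligned vector), ``log_likelihood_``, ``n_iter_``, ``converged_``.
    """

    def __init__(self, tol: float = 1e-8, max_iter: int = 1000,
                 n_restarts: int = 0, random_state: int | None = None):
        self.tol = tol
        self.max_iter = max_iter
        self.n_restarts = n_restarts
        self.random_state = random_state

    # -- internals ---------------------------------------------------------
    @staticmethod
    def _pair_indices(X: list[SnpGenotype]
                      ) -> tuple[list[str], list[np.ndarray]]:
        hap_set: set[str] = set()
        pair_lists = []
        for g in X:
            pairs = enumerate_compatible_pairs(g)
            pair_lists.append(pairs)
            for a, b in pairs:
                hap_set.update((a, b))
        haps = sorted(hap_set)
        index = {h: i for i, h in enumerate(haps)}
        encoded = [np.array([(index[a], index[b]) for a, b in pairs])
                   for pairs in pair_lists]
        return haps, encoded

    @staticmethod
    def _loglik(f: np.ndarray, encoded: list[np.ndarray]) -> float:
        ll = 0.0
        for pairs in encoded:
            pa, pb = pairs[:, 0], pairs[:, 1]
            probs = f[pa] * f[pb] * np.where(pa == pb, 1.0, 2.0)
            ll += np.log(max(probs.sum(), 1e-300))
        return ll

    def _run(self, f: np.ndarray, encoded: list[np.ndarray]
             ) -> tuple[np.ndarray, float, int, bool]:
        n = len(encoded)
        ll = self._loglik(f, encoded)
        for it in range(1, self.max_iter + 1):
            counts = np.zeros_like(f)
            for pairs in encoded:
                pa, pb = pairs[:, 0], pairs[:, 1]
                w = f[pa] * f[pb] * np.where(pa == pb, 1.0, 2.0)
                total = w.sum()
                if total <= 0:
                    w = np.full(len(pairs), 1.0 / len(pairs))
                else:
                    w = w / total
                np.add.at(counts, pa, w)
                np.add.at(counts, pb, w)
            f = counts / (2 * n)
            new_ll = self._loglik(f, encoded)
            if new_ll < ll - 1e-9:
                raise AssertionError(
                    f"EM log-likelihood decreased: {ll} -> {new_ll}")
            if new_ll - ll < self.tol:
                return f, new_ll, it, True
            ll = new_ll
        return f, ll, self.max_iter, False

    # -- sklearn surface ---------------------------------------------------
    def fit(self, X: list[SnpGenotype] | list[str], y=None
            ) -> "EMHaplotypeFrequencies":
        X = [parse_snp_genotypes(g) if isinstance(g, str) else tuple(g)
             for g in X]
        X = [g for g in X if not has_missing(g)]
        if not X:
            raise ValueError("no individuals with complete data")
        haps, encoded = self._pair_indices(X)
        f0 = np.full(len(haps), 1.0 / len(haps))
        best = self._run(f0, encoded)
        if self.n_restarts:
            rng = np.random.default_rng(self.random_state)
            for _ in range(self.n_restarts):
                start = rng.dirichlet(np.ones(len(haps)))
                cand = self._run(start, encoded)
                if cand[1] > best[1]:
                    best = cand
        self.haplotypes_ = haps
        self.frequencies_, self.log_likelihood_, self.n_iter_, \
            self.converged_ = best
        return self

    def frequency_series(self) -> pd.Series:
        return pd.Series(self.frequencies_, index=self.haplotypes_,
                         name="frequency")

    def predict(self, X: list[SnpGenotype] | list[str]
                ) -> list[tuple[str, str, float]]:
        """Maximum-posterior haplotype pair (and its posterior) per genotype.

        Ties are broken lexicographically (with a warning); genotypes with
        missing SNP calls return ``(MISSING, MISSING, nan)``.
        """
        freqs = dict(zip(self.haplotypes_, self.frequencies_))
        out = []
        for g in X:
            if isinstance(g, str):
                g = parse_snp_genotypes(g)
            out.append(phase_genotypes(g, freqs))
        return out


def em_haplotype_frequencies(genotypes: list[SnpGenotype] | list[str],
                             tol: float = 1e-8, max_iter: int = 1000,
                             ) -> tuple[pd.Series, float, int]:
    """Functional wrapper: returns (frequencies, log-likelihood, n_iter)."""
    est = EMHaplotypeFrequencies(tol=tol, max_iter=max_iter).fit(genotypes)
    return est.frequency_series(), est.log_likelihood_, est.n_iter_


def phase_genotypes(g: SnpGenotype, freqs: dict[str, float]
                    ) -> tuple[str, str, float]:
    """Assign the maximum-posterior compatible pair under HWE frequencies."""
    if has_missing(g):
        return (MISSING, MISSING, float("nan"))
    pairs = enumerate_compatible_pairs(g)
    weights = np.array([freqs.get(a, 0.0) * freqs.get(b, 0.0)
                        * (1.0 if a == b else 2.0) for a, b in pairs])
    total = weights.sum()
    if total <= 0:
        posts = np.full(len(pairs), 1.0 / len(pairs))
    else:
        posts = weights / total
    order = np.argsort(-posts, kind="stable")
    best = order[0]
    if len(order) > 1 and np.isclose(posts[order[0]], posts[order[1]]):
        warnings.warn("posterior tie while phasing; breaking "
                      "lexicographically", stacklevel=2)
    a, b = pairs[best]
    return (a, b, float(posts[best]))


def phase_table(unphased: pd.DataFrame, tol: float = 1e-8,
                max_iter: int = 1000) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Phase an unphased genotype table per (population, locus) via EM.

    Returns ``(phased genotype table, per-cell EM summary)``; the summary
    records log-likelihood, iterations, and convergence per EM run.
    """
    rows, summaries = [], []
    for (pop, locus), grp in unphased.groupby(["population", "locus"],
                                              sort=True):
        parsed = [parse_snp_genotypes(t) for t in grp["snp_genotypes"]]
        complete = [g for g in parsed if not has_missing(g)]
        if not complete:
            warnings.warn(f"({pop}, {locus}): all genotypes missing; "
                          "cell skipped", stacklevel=2)
            for s, g in zip(grp["sample"], parsed):
                rows.append((s, pop, locus, MISSING, MISSING))
            continue
        est = EMHaplotypeFrequencies(tol=tol, max_iter=max_iter).fit(complete)
        freqs = dict(zip(est.haplotypes_, est.frequencies_))
        for s, g in zip(grp["sample"], parsed):
            a, b, _ = phase_genotypes(g, freqs)
            rows.append((s, pop, locus, a, b))
        summaries.append((pop, locus, est.log_likelihood_, est.n_iter_,
                          est.converged_))
    phased = pd.DataFrame(rows, columns=GENOTYPE_COLUMNS)
    summary = pd.DataFrame(
        summaries, columns=["population", "locus", "log_likelihood",
                            "n_iter", "converged"])
    return phased, summary


def unphase_table(genotypes: pd.DataFrame) -> pd.DataFrame:
    """Strip phase from a phased genotype table (testing/round-trip aid)."""
    rows = []
    for _, row in genotypes.iterrows():
        a, b = row["allele1"], row["allele2"]
        if a == MISSING or pd.isna(a):
            gstr = MISSING
        else:
            gstr = ";".join(f"{x}/{y}" for x, y in
                            (sorted(pair) for pair in zip(a, b)))
        rows.append((row["sample"], row["population"], row["locus"], gstr))
    return pd.DataFrame(rows, columns=["sample", "population", "locus",
                                       "snp_genotypes"])
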