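"""Among-population analysis: drift distances, PCA, and genotype export.

The tau genetic distance between two populations is a drift-time estimate:
per locus

    tau_l = sum_j (p1_j - p2_j)^2 / (2 * sum_j pbar_j (1 - pbar_j)),

with ``pbar = (p1 + p2) / 2``, averaged with equal weight over loci.  Under
pure Wright-Fisher drift from a common ancestor its expectation is
approximately ``t / (2 N_e)`` — the calibration property the simulation
tests pin down.  Loci fixed for the same allele in both populations carry
no drift information (0/0) and are excluded from the average.

PCA operates on the populations x (all haplotype alleles across loci)
frequency matrix, column-centered, and reports coordinates plus explained
variance fractions.  Genotype tables can be exported in the two-row-per-
individual integer-coded format used by model-based ancestry clustering
software (missing = -9).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.decomposition import PCA

from .io import GENOTYPE_COLUMNS, MISSING
from .stats import FrequencyTable
from .trees import DistanceMatrix

__all__ = [
    "tau_distance",
    "distance_matrix",
    "PopulationPCA",
    "pca_populations",
    "export_structure_format",
    "read_structure_format",
]

STRUCTURE_MISSING = -9


def tau_distance(p1: dict[str, np.ndarray], p2: dict[str, np.ndarray],
                 ) -> float:
    """Mean per-locus tau drift distance between two populations.

    *p1* and *p2* map locus -> frequency vector on a shared allele universe.
    Only loci present in both populations are used; raises when there are
    none.
    """
    shared = sorted(set(p1) & set(p2))
    if not shared:
        raise ValueError("populations share no loci with data")
    values = []
    for locus in shared:
        a = np.asarray(p1[locus], dtype=float)
        b = np.asarray(p2[locus], dtype=float)
        if a.shape != b.shape:
            raise ValueError(f"{locus}: allele universes differ")
        pbar = (a + b) / 2.0
        denom = 2.0 * (pbar * (1.0 - pbar)).sum()
        if denom <= 0:
            continue  # both fixed for the same allele: no information
        values.append(float(np.square(a - b).sum() / denom))
    return float(np.mean(values)) if values else 0.0


def distance_matrix(freqs: FrequencyTable) -> DistanceMatrix:
    """All-pairs tau distances from a frequency table.

    Each pair uses its pairwise-complete loci; the per-pair locus count is
    carried alongside the matrix.
    """
    pops = freqs.populations
    vectors: dict[str, dict[str, np.ndarray]] = {p: {} for p in pops}
    for locus in freqs.loci:
        mat = freqs.matrix(locus)
        for pop in mat.index:
            vectors[pop][locus] = mat.loc[pop].to_numpy()
    n = len(pops)
    m = np.zeros((n, n))
    counts = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            pi, pj = vectors[pops[i]], vectors[pops[j]]
            shared = set(pi) & set(pj)
            m[i, j] = m[j, i] = tau_distance(pi, pj)
            counts[i, j] = counts[j, i] = len(shared)
    return DistanceMatrix(tuple(pops), m, counts)


class PopulationPCA(BaseEstimator):
    """PCA of populations in haplotype-allele frequency space.

    ``fit`` takes a :class:`~microhap.stats.FrequencyTable`; fitted
    attributes are ``coordinates_`` (populations x components DataFrame),
    ``explained_variance_ratio_``, and ``feature_labels_`` (the
    (locus, allele) column order).  Absent alleles enter as frequency 0.
    """

    def __init__(self, n_components: int | None = None):
        self.n_components = n_components

    @staticmethod
    def _design(freqs: FrequencyTable) -> tuple[pd.DataFrame, list]:
        blocks = []
        for locus in freqs.loci:
            mat = freqs.matrix(locus)
            mat.columns = [(locus, a) for a in mat.columns]
            blocks.append(mat)
        design = pd.concat(blocks, axis=1).fillna(0.0)
        return design, list(design.columns)

    def fit(self, X: FrequencyTable, y=None) -> "PopulationPCA":
        design, labels = self._design(X)
        n_comp = self.n_components or min(design.shape[0] - 1,
                                          design.shape[1])
        n_comp = max(1, min(n_comp, design.shape[0], design.shape[1]))
        pca = PCA(n_components=n_comp, svd_solver="full")
        coords = pca.fit_transform(design.to_numpy())  # PCA centers columns
        self.pca_ = pca
        self.feature_labels_ = labels
        self.coordinates_ = pd.DataFrame(
            coords, index=design.index,
            columns=[f"PC{i + 1}" for i in range(coords.shape[1])])
        self.explained_variance_ratio_ = pca.explained_variance_ratio_
        return self

    def transform(self, X: FrequencyTable) -> pd.DataFrame:
        design, _ = self._design(X)
        design = design.reindex(columns=self.feature_labels_, fill_value=0.0)
        coords = self.pca_.transform(design.to_numpy())
        return pd.DataFrame(
            coords, index=design.index,
            columns=[f"PC{i + 1}" for i in range(coords.shape[1])])


def pca_populations(freqs: FrequencyTable, n_components: int | None = None,
                    ) -> tuple[pd.DataFrame, np.ndarray]:
    """Coordinates and explained-variance fractions for populations."""
    est = PopulationPCA(n_components=n_components).fit(freqs)
    return est.coordinates_, est.explained_variance_ratio_


def export_structure_format(genotypes: pd.DataFrame, path: str | Path,
                            ) -> pd.DataFrame:
    """Write a two-row-per-individual integer-coded genotype file.

    Columns: sample, population index, then one column per locus (sorted);
    alleles are mapped to 1-based integers per locus, missing is -9.  The
    allele -> code mapping table is written alongside (``<path>.alleles``)
    and returned.
    """
    loci = sorted(genotypes["locus"].unique())
    codes: dict[tuple[str, str], int] = {}
    mapping_rows = []
    for locus in loci:
        sub = genotypes[genotypes["locus"] == locus]
        alleles = sorted(
            x for x in set(sub["allele1"]) | set(sub["allele2"])
            if isinstance(x, str) and x != MISSING)
        for k, allele in enumerate(alleles, start=1):
            codes[(locus, allele)] = k
            mapping_rows.append((locus, allele, k))
    pop_index = {p: i + 1 for i, p in
                 enumerate(sorted(genotypes["population"].unique()))}
    work = genotypes.copy()
    for copy, col in ((0, "allele1"), (1, "allele2")):
        keys = pd.MultiIndex.from_arrays([work["locus"], work[col]])
        work[f"code{copy}"] = pd.Series(
            keys.map(codes), index=work.index).fillna(
                STRUCTURE_MISSING).astype(int)
    samples = list(pd.unique(genotypes["sample"]))
    sample_pop = work.drop_duplicates("sample").set_index(
        "sample")["population"]
    grids = [work.pivot(index="sample", columns="locus",
                        values=f"code{copy}")
             .reindex(index=samples, columns=loci)
             .fillna(STRUCTURE_MISSING).astype(int)
             for copy in (0, 1)]
    lines = []
    for s in samples:
        prefix = [s, str(pop_index[sample_pop[s]])]
        for grid in grids:
            lines.append(" ".join(prefix + [str(v) for v in grid.loc[s]]))
    path = Path(path)
    header = " ".join(loci)
    path.write_text(header + "\n" + "\n".join(lines) + "\n")
    mapping = pd.DataFrame(mapping_rows, columns=["locus", "allele", "code"])
    mapping.to_csv(path.with_suffix(path.suffix + ".alleles"), sep="\t",
                   index=False)
    return mapping


def read_structure_format(path: str | Path) -> pd.DataFrame:
    """Re-import an exported file (round-trip testing aid).

    Returns a genotype table with integer-coded alleles as strings (missing
    back to ``.``); population labels are the 1-based indices.
    """
    lines = Path(path).read_text().strip().splitlines()
    loci = lines[0].split()
    rows: dict[tuple[str, str], list] = {}
    for line in lines[1:]:
        fields = line.split()
        sample, pop = fields[0], fields[1]
        for locus, code in zip(loci, fields[2:]):
            rows.setdefault((sample, locus), [pop]).append(code)
    out = []
    for (sample, locus), (pop, a, b) in rows.items():
        a = MISSING if a == str(STRUCTURE_MISSING) else a
        b = MISSING if b == str(STRUCTURE_MISSING) else b
        out.append((sample, pop, locus, a, b))
    return pd.DataFrame(out, columns=GENOTYPE_COLUMNS)
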