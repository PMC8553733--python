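"""Readers and writers for the plain-text table dialects used throughout.

All intermediate artifacts are TSV/JSON so pipeline stages can be mixed with
external tools.  Schemas:

* genotype table (phased): ``sample  population  locus  allele1  allele2``,
  alleles are SNP-state strings in position order, missing calls are ``.``;
* unphased genotype table: ``sample  population  locus  snp_genotypes`` with
  per-SNP unordered diploid calls like ``A/G;C/C;T/A`` (missing SNP ``./.``);
* coverage table: ``sample_id  total_reads  frac_bases_100x`` followed by one
  read-count column per locus (amplicon).
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

GENOTYPE_COLUMNS = ["sample", "population", "locus", "allele1", "allele2"]
UNPHASED_COLUMNS = ["sample", "population", "locus", "snp_genotypes"]
MISSING = "."


def read_genotypes(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = set(GENOTYPE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"genotype table missing columns {sorted(missing)}")
    return df[GENOTYPE_COLUMNS]


def write_genotypes(genotypes: pd.DataFrame, path: str | Path,
                    header_comment: str | None = None) -> None:
    _write_tsv(genotypes[GENOTYPE_COLUMNS], path, header_comment)


def read_unphased_genotypes(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = set(UNPHASED_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"unphased table missing columns {sorted(missing)}")
    return df[UNPHASED_COLUMNS]


def write_unphased_genotypes(genotypes: pd.DataFrame, path: str | Path,
                             header_comment: str | None = None) -> None:
    _write_tsv(genotypes[UNPHASED_COLUMNS], path, header_comment)


def read_coverage(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    for col in ("sample_id", "total_reads", "frac_bases_100x"):
        if col not in df.columns:
            raise ValueError(f"coverage table missing column {col!r}")
    return df


def write_coverage(coverage: pd.DataFrame, path: str | Path,
                   header_comment: str | None = None) -> None:
    _write_tsv(coverage, path, header_comment)


def coverage_locus_columns(coverage: pd.DataFrame) -> list[str]:
    """Amplicon (locus) read-count columns of a coverage table."""
    return [c for c in coverage.columns
            if c not in ("sample_id", "total_reads", "frac_bases_100x")]


def _write_tsv(df: pd.DataFrame, path: str | Path,
               header_comment: str | None) -> None:
    path = Path(path)
    with path.open("w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_vcf_genotypes(path: str | Path, population: str = "unknown",
                       locus_of=None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Extract per-locus SNP genotypes from a (plain-text) VCF.

    Variants are grouped into loci by *locus_of*, a callable
    ``(chrom, pos) -> locus name or None``; ``None`` skips the variant.
    Returns ``(phased, unphased)`` genotype tables: samples whose calls at a
    locus are all phased (``|`` separators) land in the phased table with
    alleles as SNP-state strings; samples with any unphased (``/``) call land
    in the unphased table for downstream EM phasing.  Samples with a missing
    call at any SNP of a locus are emitted as missing.
    """
    import pysam

    vcf = pysam.VariantFile(str(path))
    samples = list(vcf.header.samples)
    # per (locus, sample): list of (state1, state2, phased)
    calls: dict[str, dict[str, list[tuple[str, str, bool]]]] = {}
    for rec in vcf.fetch() if vcf.index is not None else vcf:
        locus = locus_of(rec.chrom, rec.pos) if locus_of else rec.chrom
        if locus is None:
            continue
        per_locus = calls.setdefault(locus, {s: [] for s in samples})
        for s in samples:
            call = rec.samples[s]
            alleles = call.alleles
            if alleles is None or None in alleles or len(alleles) != 2:
                per_locus[s].append((MISSING, MISSING, False))
            else:
                per_locus[s].append((alleles[0], alleles[1], bool(call.phased)))
    phased_rows, unphased_rows = [], []
    for locus, per_sample in calls.items():
        for s, snps in per_sample.items():
            if any(a == MISSING for a, _, _ in snps):
                phased_rows.append((s, population, locus, MISSING, MISSING))
            elif all(ph for _, _, ph in snps) or all(
                    a == b for a, b, _ in snps):
                h1 = "".join(a for a, _, _ in snps)
                h2 = "".join(b for _, b, _ in snps)
                phased_rows.append((s, population, locus, h1, h2))
            else:
                gstr = ";".join(f"{a}/{b}" for a, b, _ in snps)
                unphased_rows.append((s, population, locus, gstr))
    phased = pd.DataFrame(phased_rows, columns=GENOTYPE_COLUMNS)
    unphased = pd.DataFrame(unphased_rows, columns=UNPHASED_COLUMNS)
    return phased, unphased
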