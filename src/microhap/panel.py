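"""Panel definition tables: locus roster, population roster, and summaries.

A microhaplotype (MH) panel is a set of short (< ~300 bp) multi-SNP loci whose
phased SNP combinations act as multi-allelic alleles.  This module holds the
data model for the packaged 90-locus panel — locus coordinates (GRCh37,
1-based, stored as printed), per-locus SNP counts, and the published
79-population averages of the effective number of alleles (A_e) and
Rosenberg informativeness (I_n) — together with the 79-population roster,
the sequencing-cohort accounting table, and the mapping of roster world
regions onto the six biogeographic regions used for regional summaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

import pandas as pd

__all__ = [
    "LocusDefinition",
    "PopulationRecord",
    "PanelSummary",
    "PanelTable",
    "PanelParseError",
    "load_panel",
    "write_panel",
    "summarize_panel",
    "prune_loci",
    "load_populations",
    "load_region_map",
    "load_sample_accounting",
]

PANEL_COLUMNS = [
    "name", "chrom", "start_pos", "extent_bp", "snp_count",
    "avg_ae", "rosenberg_in", "in_alfred",
]
ROSTER_COLUMNS = ["abbrev", "name", "world_region", "sample_size", "source"]


class PanelParseError(ValueError):
    """Raised when a panel/roster TSV violates the documented dialect."""


@dataclass(frozen=True)
class LocusDefinition:
    """One microhaplotype locus as defined in the panel table."""

    name: str
    chrom: int
    start_pos: int          # 1-based GRCh37 position of the first SNP
    extent_bp: int          # molecular extent, base pairs
    snp_count: int          # distinct SNPs observed across the study populations
    published_avg_ae: float # average effective number of alleles, 79 populations
    published_in: float     # Rosenberg informativeness (nats), 79 populations
    in_alfred: bool

    def validate(self) -> None:
        if not (0 < self.extent_bp <= 300):
            raise PanelParseError(
                f"{self.name}: extent_bp {self.extent_bp} outside (0, 300]")
        if self.snp_count < 2:
            raise PanelParseError(f"{self.name}: snp_count {self.snp_count} < 2")
        if self.published_avg_ae < 1:
            raise PanelParseError(
                f"{self.name}: avg_ae {self.published_avg_ae} < 1")
        if not (0 <= self.published_in <= 1):
            raise PanelParseError(
                f"{self.name}: rosenberg_in {self.published_in} outside [0, 1]")
        if not (1 <= self.chrom <= 22):
            raise PanelParseError(f"{self.name}: chrom {self.chrom} not in 1..22")


@dataclass(frozen=True)
class PopulationRecord:
    """One study population: roster entry plus its biogeographic region."""

    abbreviation: str
    name: str
    world_region: str   # fine-grained roster sub-heading
    region: str         # one of the 6 biogeographic regions
    sample_size: int
    source: tuple[str, ...]

    def validate(self) -> None:
        if self.sample_size <= 0:
            raise PanelParseError(
                f"{self.abbreviation}: sample_size must be positive")
        bad = set(self.source) - {"1KG", "GA", "HGDP", "KL"}
        if bad:
            raise PanelParseError(f"{self.abbreviation}: unknown source {bad}")


@dataclass(frozen=True)
class PanelSummary:
    n_loci: int
    total_snp_count: int
    in_threshold: float
    n_below_in_threshold: int       # loci with published_in <= threshold
    max_avg_ae: tuple[str, float]   # (locus name, value)
    min_avg_ae: tuple[str, float]
    max_in: tuple[str, float]


class PanelTable:
    """Ordered collection of :class:`LocusDefinition` rows."""

    def __init__(self, loci: Iterable[LocusDefinition]):
        self.loci: list[LocusDefinition] = list(loci)
        names = [l.name for l in self.loci]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise PanelParseError(f"duplicate locus names: {sorted(dupes)}")
        for locus in self.loci:
            locus.validate()

    def __len__(self) -> int:
        return len(self.loci)

    def __iter__(self):
        return iter(self.loci)

    def __getitem__(self, name: str) -> LocusDefinition:
        for locus in self.loci:
            if locus.name == name:
                return locus
        raise KeyError(name)

    @property
    def names(self) -> list[str]:
        return [l.name for l in self.loci]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(l.name, l.chrom, l.start_pos, l.extent_bp, l.snp_count,
              l.published_avg_ae, l.published_in, l.in_alfred)
             for l in self.loci],
            columns=PANEL_COLUMNS,
        )


def _packaged(filename: str):
    return resources.files("microhap.data").joinpath(filename)


def _read_tsv(path, columns: list[str], what: str) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    except pd.errors.EmptyDataError:
        raise PanelParseError(f"{what}: empty file {path}") from None
    missing = set(columns) - set(df.columns)
    if missing:
        raise PanelParseError(f"{what}: missing columns {sorted(missing)}")
    if df.empty:
        raise PanelParseError(f"{what}: no data rows in {path}")
    return df


def load_panel(path: str | Path | None = None) -> PanelTable:
    """Load a panel TSV (packaged 90-locus table when *path* is None).

    Rows are kept in file order.  Numeric fields are validated per row and a
    :class:`PanelParseError` names the offending row on failure.
    """
    src = _packaged("panel_90mh.tsv") if path is None else Path(path)
    df = _read_tsv(src, PANEL_COLUMNS, "panel")
    loci = []
    for i, row in df.iterrows():
        try:
            loci.append(LocusDefinition(
                name=row["name"],
                chrom=int(row["chrom"]),
                start_pos=int(row["start_pos"]),
                extent_bp=int(row["extent_bp"]),
                snp_count=int(row["snp_count"]),
                published_avg_ae=float(row["avg_ae"]),
                published_in=float(row["rosenberg_in"]),
                in_alfred=str(row["in_alfred"]).strip().lower() == "true",
            ))
        except (TypeError, ValueError) as exc:
            raise PanelParseError(
                f"panel row {i + 1} ({row.get('name', '?')}): {exc}") from exc
    return PanelTable(loci)


def write_panel(panel: PanelTable, path: str | Path,
                provenance: str | None = None) -> None:
    """Write a panel TSV that :func:`load_panel` reads back field-for-field."""
    lines = []
    if provenance:
        lines.append(f"# {provenance}")
    lines.append("\t".join(PANEL_COLUMNS))
    for l in panel:
        lines.append("\t".join(map(str, [
            l.name, l.chrom, l.start_pos, l.extent_bp, l.snp_count,
            f"{l.published_avg_ae:.2f}", f"{l.published_in:.3f}",
            str(l.in_alfred).lower(),
        ])))
    Path(path).write_text("\n".join(lines) + "\n")


def summarize_panel(panel: PanelTable, in_threshold: float = 0.25) -> PanelSummary:
    """Panel-wide totals and extrema.

    ``n_below_in_threshold`` counts loci with I_n <= *in_threshold* (the
    complement of what :func:`prune_loci` retains).
    """
    if len(panel) == 0:
        raise PanelParseError("cannot summarize an empty panel")
    max_ae = max(panel, key=lambda l: l.published_avg_ae)
    min_ae = min(panel, key=lambda l: l.published_avg_ae)
    max_in = max(panel, key=lambda l: l.published_in)
    return PanelSummary(
        n_loci=len(panel),
        total_snp_count=sum(l.snp_count for l in panel),
        in_threshold=in_threshold,
        n_below_in_threshold=sum(
            1 for l in panel if l.published_in <= in_threshold),
        max_avg_ae=(max_ae.name, max_ae.published_avg_ae),
        min_avg_ae=(min_ae.name, min_ae.published_avg_ae),
        max_in=(max_in.name, max_in.published_in),
    )


def prune_loci(panel: PanelTable, in_threshold: float = 0.25) -> PanelTable:
    """Retain loci with published I_n strictly greater than *in_threshold*.

    Strict retention makes "exclude loci with I_n <= t" and this call exact
    complements; order is preserved.
    """
    if in_threshold < 0:
        raise ValueError("in_threshold must be >= 0")
    return PanelTable(l for l in panel.loci if l.published_in > in_threshold)


def load_region_map(path: str | Path | None = None
                    ) -> tuple[dict[str, str], dict[str, str]]:
    """Return (world_region -> region, population abbrev -> region override)."""
    src = _packaged("region_map.tsv") if path is None else Path(path)
    df = _read_tsv(src, ["key", "region"], "region map")
    mapping, overrides = {}, {}
    for _, row in df.iterrows():
        key = row["key"]
        if key.startswith("@"):
            overrides[key[1:]] = row["region"]
        else:
            mapping[key] = row["region"]
    if len(set(mapping.values())) != 6:
        raise PanelParseError(
            f"region map must target exactly 6 regions, got "
            f"{sorted(set(mapping.values()))}")
    return mapping, overrides


def load_populations(path: str | Path | None = None,
                     region_map_path: str | Path | None = None,
                     ) -> list[PopulationRecord]:
    """Load the population roster with six-region assignments resolved."""
    src = _packaged("populations_79.tsv") if path is None else Path(path)
    df = _read_tsv(src, ROSTER_COLUMNS, "population roster")
    mapping, overrides = load_region_map(region_map_path)
    records = []
    for i, row in df.iterrows():
        world = row["world_region"]
        abbrev = row["abbrev"]
        if world not in mapping:
            raise PanelParseError(
                f"roster row {i + 1} ({abbrev}): unmapped world region "
                f"{world!r}")
        rec = PopulationRecord(
            abbreviation=abbrev,
            name=row["name"],
            world_region=world,
            region=overrides.get(abbrev, mapping[world]),
            sample_size=int(row["sample_size"]),
            source=tuple(row["source"].split(",")),
        )
        rec.validate()
        records.append(rec)
    dupes = {r.abbreviation for r in records
             if sum(q.abbreviation == r.abbreviation for q in records) > 1}
    if dupes:
        raise PanelParseError(f"duplicate population abbreviations: {dupes}")
    return records


def load_sample_accounting(path: str | Path | None = None) -> pd.DataFrame:
    """Sequencing-cohort accounting: individuals per population per source.

    Returns a DataFrame with integer columns ``this_study``,
    ``previous_study``, ``hgdp``, boolean ``included``, and a computed
    ``total_analyzed`` (zero for groups excluded from analyses).
    """
    src = _packaged("kidd_lab_samples.tsv") if path is None else Path(path)
    df = _read_tsv(src, ["population", "this_study", "previous_study",
                         "hgdp", "included"], "sample accounting")
    for col in ("this_study", "previous_study", "hgdp"):
        df[col] = df[col].astype(int)
    df["included"] = df["included"].str.lower() == "true"
    df["total_analyzed"] = (
        (df["this_study"] + df["previous_study"] + df["hgdp"])
        * df["included"].astype(int))
    return df.reset_index(drop=True)
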