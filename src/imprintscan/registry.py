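"""Imprinted-DMR catalog loading and probe-to-region assignment.

The catalog is a TSV of genomic intervals (1-based, both ends inclusive,
GRCh37) each annotated with the parentally methylated allele (``M`` maternal,
``P`` paternal) and the overlapping gene symbols.  A curated 49-region
catalog ships with the package and is used when no path is given.

Probes from a methylation-array manifest are assigned to a DMR when their
position falls inside the region interval; catalog intervals must be
pairwise disjoint so the assignment is unambiguous.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "ImprintedDMR",
    "ProbeRecord",
    "CatalogError",
    "packaged_catalog_path",
    "load_dmr_catalog",
    "load_probe_manifest",
    "map_probes_to_dmrs",
]

CATALOG_COLUMNS = ("name", "display_name", "chrom", "start", "end", "methylated_allele", "genes")
MANIFEST_COLUMNS = ("probe_id", "chrom", "pos")


class CatalogError(ValueError):
    """Raised when a catalog or manifest violates its contract."""


@dataclass
class ImprintedDMR:
    """A single imprinted differentially methylated region."""

    name: str
    display_name: str
    chrom: str
    start: int
    end: int
    methylated_allele: str
    genes: list[str] = field(default_factory=list)
    n_probes: int = 0

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise CatalogError(f"{self.name}: start {self.start} > end {self.end}")
        if self.methylated_allele not in ("M", "P"):
            raise CatalogError(
                f"{self.name}: methylated_allele must be 'M' or 'P', got {self.methylated_allele!r}"
            )

    @property
    def length(self) -> int:
        """Interval length in bp (both ends inclusive)."""
        return self.end - self.start + 1

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos <= self.end


@dataclass
class ProbeRecord:
    """A methylation-array probe with its genomic position."""

    probe_id: str
    chrom: str
    pos: int
    dmr_name: str | None = None


def packaged_catalog_path() -> Path:
    """Path of the catalog TSV bundled with the package."""
    return Path(resources.files("imprintscan").joinpath("data/dmr_catalog.tsv"))


def load_dmr_catalog(path: str | Path | None = None) -> list[ImprintedDMR]:
    """Load a DMR catalog TSV; with no path, load the packaged 49-region catalog.

    Raises :class:`CatalogError` (with the offending row number) on missing
    columns, inverted intervals, bad allele codes or duplicate names.
    """
    if path is None:
        path = packaged_catalog_path()
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.empty and df.columns.size <= 1:
        warnings.warn(f"empty DMR catalog: {path}", stacklevel=2)
        return []
    missing = [c for c in CATALOG_COLUMNS if c not in df.columns]
    if missing:
        raise CatalogError(f"catalog {path} is missing columns: {missing}")
    if df.empty:
        warnings.warn(f"empty DMR catalog: {path}", stacklevel=2)
        return []

    catalog: list[ImprintedDMR] = []
    seen: set[str] = set()
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header is line 1
        name = row.name
        if name in seen:
            raise CatalogError(f"row {i}: duplicate DMR name {name!r}")
        seen.add(name)
        try:
            start, end = int(row.start), int(row.end)
        except ValueError as exc:
            raise CatalogError(f"row {i}: non-integer coordinates") from exc
        genes = [g for g in str(row.genes).split(";") if g]
        try:
            dmr = ImprintedDMR(
                name=name,
                display_name=row.display_name or name,
                chrom=row.chrom,
                start=start,
                end=end,
                methylated_allele=row.methylated_allele,
                genes=genes,
            )
        except CatalogError as exc:
            raise CatalogError(f"row {i}: {exc}") from exc
        catalog.append(dmr)
    return catalog


def load_probe_manifest(path: str | Path) -> pd.DataFrame:
    """Load a probe manifest TSV (probe_id, chrom, pos); probe_id must be unique."""
    df = pd.read_csv(path, sep="\t", dtype={"probe_id": str, "chrom": str, "pos": int})
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise CatalogError(f"manifest {path} is missing columns: {missing}")
    if df["probe_id"].duplicated().any():
        dups = df.loc[df["probe_id"].duplicated(), "probe_id"].tolist()
        raise CatalogError(f"duplicate probe_id in manifest: {dups[:5]}")
    return df[list(MANIFEST_COLUMNS)]


def _check_disjoint(catalog: Sequence[ImprintedDMR]) -> None:
    by_chrom: dict[str, list[ImprintedDMR]] = {}
    for dmr in catalog:
        by_chrom.setdefault(dmr.chrom, []).append(dmr)
    for chrom, dmrs in by_chrom.items():
        dmrs = sorted(dmrs, key=lambda d: d.start)
        for a, b in zip(dmrs, dmrs[1:]):
            if b.start <= a.end:
                raise CatalogError(
                    f"catalog intervals overlap on {chrom}: {a.name} and {b.name}"
                )


def map_probes_to_dmrs(
    probes: pd.DataFrame | Iterable[ProbeRecord],
    catalog: Sequence[ImprintedDMR],
) -> tuple[pd.DataFrame, pd.Series]:
    """Assign each probe to the DMR whose interval contains its position.

    Parameters
    ----------
    probes
        Manifest DataFrame (probe_id, chrom, pos) or an iterable of
        :class:`ProbeRecord`.
    catalog
        DMR intervals; must be pairwise disjoint.

    Returns
    -------
    (mapped, counts)
        ``mapped`` is the manifest with a ``dmr_name`` column (``NA`` where a
        probe falls in no DMR); ``counts`` is the per-DMR probe count indexed
        by DMR name, including zero-probe DMRs.  ``n_probes`` is also filled
        in on the catalog entries.
    """
    if not isinstance(probes, pd.DataFrame):
        probes = pd.DataFrame(
            [(p.probe_id, p.chrom, p.pos) for p in probes],
            columns=list(MANIFEST_COLUMNS),
        )
    _check_disjoint(catalog)

    mapped = probes.copy()
    mapped["dmr_name"] = pd.NA
    for dmr in catalog:
        inside = (
            (mapped["chrom"] == dmr.chrom)
            & (mapped["pos"] >= dmr.start)
            & (mapped["pos"] <= dmr.end)
        )
        mapped.loc[inside, "dmr_name"] = dmr.name

    counts = pd.Series(0, index=[d.name for d in catalog], dtype=int, name="n_probes")
    observed = mapped["dmr_name"].value_counts()
    counts.update(observed)
    for dmr in catalog:
        dmr.n_probes = int(counts[dmr.name])
    empty = counts.index[counts == 0].tolist()
    if empty:
        warnings.warn(f"{len(empty)} DMRs have zero probes: {empty[:5]}", stacklevel=2)
    return mapped, counts
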