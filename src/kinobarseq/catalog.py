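"""Barcoded deletion-strain catalog and multiplexing sample sheet.

Every strain in a homozygous diploid yeast deletion pool carries a unique
20-mer UPTAG barcode; pooled experiments are multiplexed with 6-mer indexing
tags embedded in the amplification primers, one (forward, reverse) tag pair
per kinase experiment.  This module loads, validates and queries both
registries from plain TSV files.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

UPTAG_LENGTH = 20
INDEX_TAG_LENGTH = 6

_DNA_RE = re.compile(r"^[ACGT]+$")


class CatalogError(ValueError):
    """Raised when a catalog or sample sheet violates its invariants."""


def _clean_sequence(seq: str, length: int, what: str, context: str) -> str:
    """Upper-case a DNA string and enforce alphabet and length."""
    seq = str(seq).strip().upper()
    if not _DNA_RE.match(seq):
        raise CatalogError(
            f"{what} {seq!r} ({context}) contains characters outside A/C/G/T"
        )
    if len(seq) != length:
        raise CatalogError(
            f"{what} {seq!r} ({context}) has length {len(seq)}, expected {length}"
        )
    return seq


@dataclass(frozen=True)
class DeletionStrain:
    """One barcoded deletion strain: identifier, deleted ORF, UPTAG barcode."""

    strain_id: str
    yeast_gene: str
    uptag: str

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "uptag",
            _clean_sequence(self.uptag, UPTAG_LENGTH, "uptag", f"strain {self.strain_id}"),
        )


class BarcodeCatalog:
    """Ordered registry of deletion strains with unique UPTAG barcodes.

    The full-scale pool holds 4,653 uniquely barcoded clones, but any
    non-empty catalog is accepted.  Lookup by barcode is a bijection onto
    strain identifiers.
    """

    def __init__(self, strains: Iterable[DeletionStrain]):
        self.strains: list[DeletionStrain] = list(strains)
        if not self.strains:
            raise CatalogError("catalog must contain at least one strain")
        self._by_id: dict[str, DeletionStrain] = {}
        self._by_uptag: dict[str, DeletionStrain] = {}
        for s in self.strains:
            if s.strain_id in self._by_id:
                raise CatalogError(f"duplicate strain_id {s.strain_id!r}")
            other = self._by_uptag.get(s.uptag)
            if other is not None:
                raise CatalogError(
                    f"duplicate uptag {s.uptag!r} shared by strains "
                    f"{other.strain_id!r} and {s.strain_id!r}"
                )
            self._by_id[s.strain_id] = s
            self._by_uptag[s.uptag] = s

    @property
    def size(self) -> int:
        return len(self.strains)

    def __len__(self) -> int:
        return len(self.strains)

    def __iter__(self):
        return iter(self.strains)

    @property
    def strain_ids(self) -> list[str]:
        return [s.strain_id for s in self.strains]

    def lookup_uptag(self, uptag: str) -> DeletionStrain | None:
        return self._by_uptag.get(uptag.upper())

    def get(self, strain_id: str) -> DeletionStrain:
        return self._by_id[strain_id]

    def gene_of(self, strain_id: str) -> str:
        """Deleted ORF for a strain; falls back to the strain id itself."""
        s = self._by_id.get(strain_id)
        return s.yeast_gene if s is not None else strain_id

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "strain_id": [s.strain_id for s in self.strains],
                "yeast_gene": [s.yeast_gene for s in self.strains],
                "uptag": [s.uptag for s in self.strains],
            }
        )


class SampleSheet:
    """Kinase experiment → (forward tag, reverse tag) demultiplexing map.

    Tag pairs must be pairwise distinct across kinases, otherwise reads
    could not be attributed to an experiment.
    """

    def __init__(self, entries: Mapping[str, tuple[str, str]]):
        self.entries: dict[str, tuple[str, str]] = {}
        seen: dict[tuple[str, str], str] = {}
        for kinase, (fwd, rev) in entries.items():
            fwd = _clean_sequence(fwd, INDEX_TAG_LENGTH, "fwd_tag", f"kinase {kinase}")
            rev = _clean_sequence(rev, INDEX_TAG_LENGTH, "rev_tag", f"kinase {kinase}")
            if (fwd, rev) in seen:
                raise CatalogError(
                    f"tag pair ({fwd}, {rev}) assigned to both "
                    f"{seen[(fwd, rev)]!r} and {kinase!r}"
                )
            seen[(fwd, rev)] = kinase
            self.entries[str(kinase)] = (fwd, rev)
        if not self.entries:
            raise CatalogError("sample sheet must contain at least one kinase")

    @property
    def kinases(self) -> list[str]:
        return list(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def __getitem__(self, kinase: str) -> tuple[str, str]:
        return self.entries[kinase]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "kinase": list(self.entries),
                "fwd_tag": [t[0] for t in self.entries.values()],
                "rev_tag": [t[1] for t in self.entries.values()],
            }
        )


def _read_tsv(path: str | Path, required: list[str], what: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"{what} file not found: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise CatalogError(f"{what} {path} is missing columns: {', '.join(missing)}")
    return df


def load_catalog(path: str | Path) -> BarcodeCatalog:
    """Read a strain catalog TSV with columns strain_id, yeast_gene, uptag."""
    df = _read_tsv(path, ["strain_id", "yeast_gene", "uptag"], "catalog")
    try:
        return BarcodeCatalog(
            DeletionStrain(row.strain_id, row.yeast_gene, row.uptag)
            for row in df.itertuples(index=False)
        )
    except CatalogError as exc:
        raise CatalogError(f"{path}: {exc}") from None


def write_catalog(catalog: BarcodeCatalog, path: str | Path) -> None:
    catalog.to_frame().to_csv(path, sep="\t", index=False)


def load_sample_sheet(path: str | Path) -> SampleSheet:
    """Read a sample sheet TSV with columns kinase, fwd_tag, rev_tag."""
    df = _read_tsv(path, ["kinase", "fwd_tag", "rev_tag"], "sample sheet")
    dup = df["kinase"][df["kinase"].duplicated()]
    if not dup.empty:
        raise CatalogError(f"{path}: duplicate kinase entries: {sorted(set(dup))}")
    try:
        return SampleSheet(
            {row.kinase: (row.fwd_tag, row.rev_tag) for row in df.itertuples(index=False)}
        )
    except CatalogError as exc:
        raise CatalogError(f"{path}: {exc}") from None


def write_sample_sheet(sheet: SampleSheet, path: str | Path) -> None:
    sheet.to_frame().to_csv(path, sep="\t", index=False)
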