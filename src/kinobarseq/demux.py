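"""Amplicon read parsing, demultiplexing and UPTAG barcode counting.

Reads from the multiplexed Bar-seq amplicon have the layout (sequenced
strand, 5'→3'):

    G <fwd 6-mer tag> GATGTCCACGAGGTCTCT <20-mer UPTAG>
      revcomp(GTCGACCTGCAGCGTACG) <revcomp of rev 6-mer tag> G

The 18-mer common primers flank the barcode in every read, so the forward
primer is used as an anchor: the six bases 5' of it are the experiment tag
and the twenty bases 3' of it are the strain barcode.  Reads that fail any
step are never dropped silently — each failure mode is tallied in per-kinase
QC so that read totals always reconcile.
"""

from __future__ import annotations

import gzip
import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .catalog import BarcodeCatalog, SampleSheet

FWD_ANCHOR = "GATGTCCACGAGGTCTCT"
REV_ANCHOR = "GTCGACCTGCAGCGTACG"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# read statuses, in QC-report order
STATUS_OK = "ok"
STATUS_NO_ANCHOR = "no_anchor"
STATUS_AMBIGUOUS_TAG = "ambiguous_tag"
STATUS_AMBIGUOUS_BARCODE = "ambiguous_barcode"
STATUS_UNMATCHED_BARCODE = "unmatched_barcode"
STATUSES = (
    STATUS_OK,
    STATUS_NO_ANCHOR,
    STATUS_AMBIGUOUS_TAG,
    STATUS_AMBIGUOUS_BARCODE,
    STATUS_UNMATCHED_BARCODE,
)

UNASSIGNED = "(unassigned)"


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


def hamming(a: str, b: str) -> int:
    """Hamming distance between equal-length strings."""
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal-length strings")
    return sum(x != y for x, y in zip(a, b))


@dataclass(frozen=True)
class ReadLayout:
    """Structure of one amplicon read.

    ``min_anchor_offset`` is the earliest position at which the forward
    anchor may start: one leading template base plus the 6-mer tag.
    """

    fwd_anchor: str = FWD_ANCHOR
    rev_anchor: str = REV_ANCHOR
    tag_len: int = 6
    barcode_len: int = 20

    def __post_init__(self) -> None:
        if self.tag_len <= 0 or self.barcode_len <= 0:
            raise ValueError("tag_len and barcode_len must be positive")

    @property
    def min_anchor_offset(self) -> int:
        return self.tag_len + 1

    @property
    def min_read_len(self) -> int:
        """Shortest read that still yields tag + anchor + barcode."""
        return self.min_anchor_offset + len(self.fwd_anchor) + self.barcode_len


DEFAULT_LAYOUT = ReadLayout()


@dataclass
class ParsedRead:
    """Outcome of structural parsing of a single read."""

    status: str
    fwd_tag: str | None = None
    barcode: str | None = None
    rev_tag: str | None = None


def _find_anchor(seq: str, anchor: str, min_offset: int, max_mm: int) -> int | None:
    """Offset of the unique best anchor match, or None.

    Exact search first; with a mismatch budget, all offsets are scanned and
    a tie at the minimal distance is treated as no match (an ambiguous
    anchor cannot place the tag or barcode reliably).
    """
    pos = seq.find(anchor, min_offset)
    if pos != -1:
        # an exact hit is the unique minimum unless a second exact hit exists
        return None if seq.find(anchor, pos + 1) != -1 else pos
    if max_mm == 0:
        return None
    best, best_pos, ties = max_mm + 1, None, 0
    la = len(anchor)
    for off in range(min_offset, len(seq) - la + 1):
        d = hamming(seq[off : off + la], anchor)
        if d < best:
            best, best_pos, ties = d, off, 1
        elif d == best:
            ties += 1
    if best > max_mm or ties > 1:
        return None
    return best_pos


def parse_read(
    seq: str, layout: ReadLayout = DEFAULT_LAYOUT, max_anchor_mm: int = 0
) -> ParsedRead:
    """Locate the forward anchor and extract tag, barcode and reverse tag.

    The reverse tag is extracted only when the read is long enough to reach
    it and the reverse anchor verifies within the same mismatch budget;
    otherwise it is left absent and demultiplexing falls back to the forward
    tag alone.  Failures are encoded in ``status``, never raised.
    """
    seq = seq.strip().upper()
    if len(seq) < layout.min_read_len:
        return ParsedRead(STATUS_NO_ANCHOR)
    off = _find_anchor(seq, layout.fwd_anchor, layout.min_anchor_offset, max_anchor_mm)
    if off is None:
        return ParsedRead(STATUS_NO_ANCHOR)
    fwd_tag = seq[off - layout.tag_len : off]
    bc_start = off + len(layout.fwd_anchor)
    barcode = seq[bc_start : bc_start + layout.barcode_len]
    if len(barcode) < layout.barcode_len:
        return ParsedRead(STATUS_NO_ANCHOR)
    rev_tag = None
    ra = revcomp(layout.rev_anchor)
    ra_start = bc_start + layout.barcode_len
    tag_end = ra_start + len(ra) + layout.tag_len
    if len(seq) >= tag_end:
        if hamming(seq[ra_start : ra_start + len(ra)], ra) <= max_anchor_mm:
            rev_tag = revcomp(seq[ra_start + len(ra) : tag_end])
    return ParsedRead(STATUS_OK, fwd_tag=fwd_tag, barcode=barcode, rev_tag=rev_tag)


def assign_kinase(
    parsed: ParsedRead, sheet: SampleSheet, max_tag_mm: int = 0
) -> str | None:
    """Demultiplex a parsed read to a kinase experiment by its tag pair.

    With both tags available the combined Hamming distance to each sheet
    entry is used; with only the forward tag, it must identify a unique
    entry.  Ties at the minimal distance, or a minimum exceeding
    ``max_tag_mm``, yield None (an unassigned read, tallied in QC).
    """
    if parsed.status != STATUS_OK or parsed.fwd_tag is None:
        return None
    best, best_kinase, ties = max_tag_mm + 1, None, 0
    for kinase, (fwd, rev) in sheet.entries.items():
        d = hamming(parsed.fwd_tag, fwd)
        if parsed.rev_tag is not None:
            d += hamming(parsed.rev_tag, rev)
        if d < best:
            best, best_kinase, ties = d, kinase, 1
        elif d == best:
            ties += 1
    if best > max_tag_mm or ties > 1:
        return None
    return best_kinase


def match_barcode(
    barcode: str, catalog: BarcodeCatalog, max_bc_mm: int = 0
) -> str | None:
    """Strain whose UPTAG is uniquely nearest the observed barcode.

    Returns the strain_id of the unique catalog barcode within
    ``max_bc_mm`` mismatches; ties or no hit return None.
    """
    barcode = barcode.upper()
    exact = catalog.lookup_uptag(barcode)
    if exact is not None:
        return exact.strain_id  # distance 0 is always the unique minimum
    if max_bc_mm == 0:
        return None
    best, best_id, ties = max_bc_mm + 1, None, 0
    for strain in catalog:
        d = hamming(barcode, strain.uptag)
        if d < best:
            best, best_id, ties = d, strain.strain_id, 1
        elif d == best:
            ties += 1
    if best > max_bc_mm or ties > 1:
        return None
    return best_id


class CountMatrix:
    """Raw UPTAG counts, strains × kinase experiments, with per-kinase QC.

    ``counts`` is a DataFrame indexed by strain_id with one column per
    kinase; ``qc`` tallies each read status per kinase plus an
    ``(unassigned)`` row for reads whose experiment could not be determined.
    """

    def __init__(self, counts: pd.DataFrame, qc: pd.DataFrame | None = None):
        if (counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        self.counts = counts.astype(np.int64)
        if qc is None:
            qc = pd.DataFrame(
                0,
                index=list(counts.columns) + [UNASSIGNED],
                columns=list(STATUSES),
                dtype=np.int64,
            )
        self.qc = qc

    @property
    def strain_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def kinases(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def total_reads(self) -> int:
        """All reads seen, assigned or not (from QC tallies)."""
        return int(self.qc.values.sum())

    def to_tsv(self, path: str | Path) -> None:
        self.counts.to_csv(path, sep="\t", index_label="strain_id")

    def qc_to_tsv(self, path: str | Path) -> None:
        self.qc.to_csv(path, sep="\t", index_label="kinase")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CountMatrix":
        df = pd.read_csv(path, sep="\t", index_col="strain_id")
        return cls(df)


def _open_fastq(path: str | Path) -> Iterator[str]:
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as handle:
        for _title, seq, _qual in FastqGeneralIterator(handle):
            yield seq


def count_reads(
    reads: str | Path | Iterable[str],
    catalog: BarcodeCatalog,
    sheet: SampleSheet,
    layout: ReadLayout = DEFAULT_LAYOUT,
    max_tag_mm: int = 0,
    max_bc_mm: int = 0,
    max_anchor_mm: int = 0,
) -> CountMatrix:
    """Count UPTAG reads per (strain, kinase) from a FASTQ file or sequences.

    ``reads`` may be a FASTQ path (plain or .gz) or any iterable of read
    sequences.  Counting is order-invariant and conserves reads: for every
    kinase, ok + failure tallies equal the reads assigned to it, and summing
    the QC table recovers the total input read count.
    """
    if isinstance(reads, (str, Path)):
        reads = _open_fastq(reads)

    kinases = sheet.kinases
    kin_index = {k: i for i, k in enumerate(kinases)}
    strain_index = {s: i for i, s in enumerate(catalog.strain_ids)}
    mat = np.zeros((len(strain_index), len(kinases)), dtype=np.int64)
    qc: dict[str, Counter] = {k: Counter() for k in kinases}
    qc[UNASSIGNED] = Counter()

    # memoised resolution of observed (tag pair → kinase) and (barcode → strain);
    # the distinct-key space is tiny next to the read count
    assign_cache: dict[tuple[str, str | None], str | None] = {}
    barcode_cache: dict[str, tuple[str | None, str]] = {}

    n_reads = 0
    for seq in reads:
        n_reads += 1
        parsed = parse_read(seq, layout, max_anchor_mm)
        if parsed.status != STATUS_OK:
            qc[UNASSIGNED][parsed.status] += 1
            continue
        key = (parsed.fwd_tag, parsed.rev_tag)
        if key in assign_cache:
            kinase = assign_cache[key]
        else:
            kinase = assign_kinase(parsed, sheet, max_tag_mm)
            assign_cache[key] = kinase
        if kinase is None:
            qc[UNASSIGNED][STATUS_AMBIGUOUS_TAG] += 1
            continue
        cached = barcode_cache.get(parsed.barcode)
        if cached is None:
            strain = match_barcode(parsed.barcode, catalog, max_bc_mm)
            if strain is not None:
                cached = (strain, STATUS_OK)
            else:
                # distinguish "nothing close" from "tie" for QC purposes
                dists = [hamming(parsed.barcode, s.uptag) for s in catalog]
                dmin = min(dists)
                status = (
                    STATUS_AMBIGUOUS_BARCODE
                    if dmin <= max_bc_mm and dists.count(dmin) > 1
                    else STATUS_UNMATCHED_BARCODE
                )
                cached = (None, status)
            barcode_cache[parsed.barcode] = cached
        strain, status = cached
        if strain is None:
            qc[kinase][status] += 1
            continue
        mat[strain_index[strain], kin_index[kinase]] += 1
        qc[kinase][STATUS_OK] += 1

    if n_reads == 0:
        warnings.warn("empty read stream: returning an all-zero count matrix")

    counts = pd.DataFrame(mat, index=catalog.strain_ids, columns=kinases)
    qc_df = pd.DataFrame(
        [[qc[k].get(s, 0) for s in STATUSES] for k in kinases + [UNASSIGNED]],
        index=kinases + [UNASSIGNED],
        columns=list(STATUSES),
        dtype=np.int64,
    )
    return CountMatrix(counts, qc_df)
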