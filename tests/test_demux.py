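"""Read parsing, tag demultiplexing, barcode matching and counting."""

import random

import numpy as np
import pytest

from kinobarseq import (
    ParsedRead,
    ReadLayout,
    assign_kinase,
    count_reads,
    match_barcode,
    parse_read,
)
from kinobarseq.demux import (
    FWD_ANCHOR,
    REV_ANCHOR,
    STATUS_NO_ANCHOR,
    STATUS_OK,
    UNASSIGNED,
    hamming,
    revcomp,
)

BARCODE = "ACGTACGTACGTACGTACGT"


def make_read(fwd_tag="AACCTT", barcode=BARCODE, rev_tag="TTGGAA"):
    """Assemble a full amplicon read on the sequenced strand."""
    return "G" + fwd_tag + FWD_ANCHOR + barcode + revcomp(REV_ANCHOR) + revcomp(rev_tag) + "G"


def brute_force_anchor_hits(seq, anchor, min_offset):
    """Independent oracle: all offsets achieving the minimal mismatch count."""
    dists = {
        off: hamming(seq[off : off + len(anchor)], anchor)
        for off in range(min_offset, len(seq) - len(anchor) + 1)
    }
    best = min(dists.values())
    return [off for off, d in dists.items() if d == best], best


def test_parse_full_read_extracts_all_fields():
    parsed = parse_read(make_read())
    assert parsed.status == STATUS_OK
    assert parsed.fwd_tag == "AACCTT"
    assert parsed.barcode == BARCODE
    assert parsed.rev_tag == "TTGGAA"


def test_parse_without_reverse_segment_still_ok():
    # early sequencers may not reach the reverse tag; forward structure suffices
    read = ("G" + "AACCTT" + FWD_ANCHOR + BARCODE)
    parsed = parse_read(read)
    assert parsed.status == STATUS_OK
    assert parsed.barcode == BARCODE
    assert parsed.rev_tag is None


def test_corrupt_reverse_anchor_drops_rev_tag_only():
    read = make_read()
    pos = 1 + 6 + len(FWD_ANCHOR) + 20 + 3  # inside the reverse anchor
    read = read[:pos] + ("A" if read[pos] != "A" else "C") + read[pos + 1 :]
    parsed = parse_read(read)
    assert parsed.status == STATUS_OK and parsed.rev_tag is None


def test_missing_anchor_and_short_reads_fail():
    assert parse_read("ACGT" * 20).status == STATUS_NO_ANCHOR
    assert parse_read("G" + "AACCTT" + FWD_ANCHOR[:-1]).status == STATUS_NO_ANCHOR
    # anchor present but too early to leave room for the 6-mer tag
    assert parse_read(FWD_ANCHOR + BARCODE).status == STATUS_NO_ANCHOR


def test_ambiguous_anchor_is_a_failure():
    # two exact anchor occurrences downstream of the tag region
    seq = "G" + "AACCTT" + FWD_ANCHOR + FWD_ANCHOR + BARCODE
    hits, best = brute_force_anchor_hits(seq, FWD_ANCHOR, min_offset=7)
    assert best == 0 and len(hits) == 2  # oracle confirms two minimal hits
    assert parse_read(seq).status == STATUS_NO_ANCHOR


def test_anchor_with_one_mismatch_recovered_when_configured():
    read = make_read()
    mismatched = read[:10] + ("A" if read[10] != "A" else "C") + read[11:]
    assert parse_read(mismatched, max_anchor_mm=0).status == STATUS_NO_ANCHOR
    parsed = parse_read(mismatched, max_anchor_mm=1)
    assert parsed.status == STATUS_OK and parsed.barcode == BARCODE


def test_assign_kinase_exact_and_strictness(toy_sheet):
    parsed = ParsedRead(STATUS_OK, fwd_tag="AACCTT", barcode=BARCODE, rev_tag="TTGGAA")
    assert assign_kinase(parsed, toy_sheet, max_tag_mm=0) == "KIN_A"
    # one mismatched base with a zero budget -> unassigned
    off = ParsedRead(STATUS_OK, fwd_tag="TACCTT", barcode=BARCODE, rev_tag="TTGGAA")
    assert assign_kinase(off, toy_sheet, max_tag_mm=0) is None
    assert assign_kinase(off, toy_sheet, max_tag_mm=1) == "KIN_A"


def test_assign_kinase_tie_is_unassigned():
    from kinobarseq import SampleSheet

    sheet = SampleSheet({"K1": ("AAAAAA", "CCCCCC"), "K2": ("AAAAAT", "CCCCCC")})
    # fwd tag at distance 1 from both entries
    parsed = ParsedRead(STATUS_OK, fwd_tag="AAAAAG", barcode=BARCODE, rev_tag="CCCCCC")
    assert assign_kinase(parsed, sheet, max_tag_mm=1) is None


def test_assign_kinase_matches_enumeration_oracle(toy_sheet):
    """Randomised check against exhaustive Hamming enumeration of the sheet."""
    rng = random.Random(7)
    bases = "ACGT"
    for max_mm in (0, 1):
        for _ in range(300):
            fwd = "".join(rng.choice(bases) for _ in range(6))
            rev = "".join(rng.choice(bases) for _ in range(6))
            parsed = ParsedRead(STATUS_OK, fwd_tag=fwd, barcode=BARCODE, rev_tag=rev)
            dists = {
                k: hamming(fwd, f) + hamming(rev, r)
                for k, (f, r) in toy_sheet.entries.items()
            }
            best = min(dists.values())
            expect = None
            if best <= max_mm and list(dists.values()).count(best) == 1:
                expect = min(k for k, d in dists.items() if d == best)
            assert assign_kinase(parsed, toy_sheet, max_mm) == expect


def mutate(seq, positions, rng):
    out = list(seq)
    for pos in positions:
        out[pos] = rng.choice([b for b in "ACGT" if b != out[pos]])
    return "".join(out)


def test_match_barcode_against_exhaustive_oracle(toy_catalog):
    """Mutated barcodes resolved identically by scan and exhaustive oracle."""
    rng = random.Random(11)
    uptags = {s.strain_id: s.uptag for s in toy_catalog}
    for max_mm in (0, 1, 2):
        for _ in range(200):
            true_id = rng.choice(list(uptags))
            k = rng.randint(0, 3)
            barcode = mutate(uptags[true_id], rng.sample(range(20), k), rng)
            dists = {sid: hamming(barcode, u) for sid, u in uptags.items()}
            best = min(dists.values())
            expect = None
            if best <= max_mm and list(dists.values()).count(best) == 1:
                expect = next(sid for sid, d in dists.items() if d == best)
            assert match_barcode(barcode, toy_catalog, max_mm) == expect


def test_barcode_equidistant_tie_matches_nobody():
    from kinobarseq import BarcodeCatalog, DeletionStrain

    a = "A" * 20
    b = "A" * 18 + "CC"  # distance 2 from a
    cat = BarcodeCatalog([DeletionStrain("sa", "ga", a), DeletionStrain("sb", "gb", b)])
    middle = "A" * 18 + "CA"  # distance 1 from both
    assert hamming(middle, a) == 1 and hamming(middle, b) == 1
    assert match_barcode(middle, cat, max_bc_mm=1) is None
    assert match_barcode(middle, cat, max_bc_mm=2) is None


def test_count_reads_single_cell_and_conservation(toy_catalog, toy_sheet):
    strain = toy_catalog.strains[3]
    good = [make_read(barcode=strain.uptag) for _ in range(100)]
    junk = ["T" * 70] * 10  # anchorless
    cm = count_reads(good + junk, toy_catalog, toy_sheet)
    assert cm.counts.at[strain.strain_id, "KIN_A"] == 100
    assert cm.counts.values.sum() == 100
    assert cm.qc.at[UNASSIGNED, STATUS_NO_ANCHOR] == 10
    assert cm.total_reads == 110  # every read lands in exactly one tally


def test_count_reads_is_order_invariant(toy_catalog, toy_sheet):
    rng = random.Random(3)
    reads = []
    for strain in toy_catalog.strains[:4]:
        for tag_pair, n in (("KIN_A", 5), ("KIN_B", 8)):
            fwd, rev = toy_sheet[tag_pair]
            reads += [make_read(fwd, strain.uptag, rev)] * n
    cm1 = count_reads(list(reads), toy_catalog, toy_sheet)
    rng.shuffle(reads)
    cm2 = count_reads(reads, toy_catalog, toy_sheet)
    assert cm1.counts.equals(cm2.counts)
    assert cm1.qc.equals(cm2.qc)


def test_exact_counting_equals_naive_lookup_oracle(toy_catalog, toy_sheet):
    """With zero mismatch budgets, counting reduces to exact string lookup."""
    rng = random.Random(5)
    uptag_to_id = {s.uptag: s.strain_id for s in toy_catalog}
    pair_to_kinase = {pair: k for k, pair in toy_sheet.entries.items()}
    naive = {}
    reads = []
    for _ in range(500):
        strain = rng.choice(toy_catalog.strains)
        kinase = rng.choice(toy_sheet.kinases)
        fwd, rev = toy_sheet[kinase]
        reads.append(make_read(fwd, strain.uptag, rev))
        key = (uptag_to_id[strain.uptag], pair_to_kinase[(fwd, rev)])
        naive[key] = naive.get(key, 0) + 1
    cm = count_reads(reads, toy_catalog, toy_sheet)
    for (sid, kin), n in naive.items():
        assert cm.counts.at[sid, kin] == n
    assert cm.counts.values.sum() == 500


def test_empty_stream_warns_and_returns_zero_matrix(toy_catalog, toy_sheet):
    with pytest.warns(UserWarning, match="empty"):
        cm = count_reads([], toy_catalog, toy_sheet)
    assert cm.counts.values.sum() == 0
    assert cm.counts.shape == (toy_catalog.size, len(toy_sheet))


def test_layout_validation():
    with pytest.raises(ValueError):
        ReadLayout(tag_len=0)
    layout = ReadLayout()
    assert layout.min_anchor_offset == 7
    assert layout.min_read_len == 45  # leading base + tag + anchor + barcode
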