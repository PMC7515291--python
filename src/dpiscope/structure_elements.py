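"""Structural-element pipeline: stringent disorder consensus, segment
extraction, linker statistics, residue-overlap audit and co-occurrence
partitioning.

Disorder calling is deliberately conservative.  Two per-residue disorder
predictions are intersected, and residues falling in oligomeric fibrillar
motifs — coiled coils (either of two predictors), single α-helices, collagen
triple helices — are removed, because such ordered-in-complex segments are a
notorious source of false-positive disorder.  The remaining residues represent
segments plausibly disordered under cellular conditions.

Qualifying intrinsically disordered regions (IDRs) and coiled coils must be
*longer than* a minimum length (default 10, i.e. ≥ 11 residues); transmembrane
helices and domains qualify at any length.  Proteins are then partitioned into
twelve element-combination categories: the ten printed categories of the
co-occurrence analysis plus two residual ones (``idr_other_combo``, ``none``)
so the partition is exhaustive.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .core_io import ProteinRecord, ResidueTrack

#: Segment kinds recognised by :class:`SegmentSet`.
SEGMENT_KINDS = ("IDR", "CC", "TM", "DOMAIN", "LCR", "SAH", "COLLAGEN")

#: The twelve co-occurrence categories (ten printed + two residuals).
CATEGORIES = (
    "idr_only",
    "cc_only",
    "tm_only",
    "domain_only",
    "idr_cc",
    "idr_tm",
    "idr_domain",
    "idr_cc_domain",
    "all_four",
    "ordered_combo",
    "idr_other_combo",
    "none",
)

#: Default track names consumed by :func:`element_flags`.
TRACKS_DISORDER = ("idr_iupred", "idr_vsl2b")
TRACKS_CC = ("cc_coils", "cc_paircoil")
TRACKS_FIBRILLAR_EXTRA = ("sah", "collagen")
TRACK_TM = "tm"
TRACK_DOMAIN = "domain"

DEFAULT_MIN_LEN = 10  # "longer than 10 residues": qualifying length >= 11


@dataclass
class SegmentSet:
    """Sorted, pairwise-disjoint 1-based inclusive segments of one kind."""

    kind: str
    segments: list[tuple[int, int]]
    protein_length: int

    def __post_init__(self) -> None:
        if self.kind not in SEGMENT_KINDS:
            raise ValueError(f"unknown segment kind {self.kind!r}")
        prev_end = 0
        for s, e in self.segments:
            if s > e:
                raise ValueError(f"segment {s}-{e}: start > end")
            if s <= prev_end:
                raise ValueError(f"segments overlap or are unsorted at {s}-{e}")
            if e > self.protein_length:
                raise ValueError(f"segment {s}-{e} outside protein")
            prev_end = e

    def __len__(self) -> int:
        return len(self.segments)

    def residues(self) -> int:
        return sum(e - s + 1 for s, e in self.segments)


@dataclass(frozen=True)
class ElementFlags:
    """Presence of at least one qualifying segment per element type."""

    has_idr: bool
    has_cc: bool
    has_tm: bool
    has_domain: bool


def _check_lengths(*tracks: ResidueTrack) -> int:
    lengths = {t.length for t in tracks}
    if len(lengths) != 1:
        raise ValueError(f"track length mismatch: {sorted(lengths)}")
    return lengths.pop()


def fibrillar_union(
    cc_a: ResidueTrack,
    cc_b: ResidueTrack,
    sah: ResidueTrack,
    collagen: ResidueTrack,
) -> ResidueTrack:
    """Permissive union of oligomeric-fibrillar-motif predictions.

    Positionwise OR of the two coiled-coil tracks, the single-α-helix track and
    the collagen track.
    """
    _check_lengths(cc_a, cc_b, sah, collagen)
    bits = cc_a.bits | cc_b.bits | sah.bits | collagen.bits
    return ResidueTrack.from_bits("fibrillar", bits)


def consensus_disorder(
    iupred: ResidueTrack, vsl2b: ResidueTrack, fibrillar: ResidueTrack
) -> ResidueTrack:
    """Stringent disorder consensus: (pred A AND pred B) AND NOT fibrillar."""
    _check_lengths(iupred, vsl2b, fibrillar)
    bits = (iupred.bits & vsl2b.bits) & (1 - fibrillar.bits)
    return ResidueTrack.from_bits("idr_consensus", bits)


def extract_segments(
    track: ResidueTrack, min_len: int = 0, kind: str = "IDR"
) -> SegmentSet:
    """Maximal runs of 1s strictly longer than ``min_len`` residues.

    ``min_len=10`` keeps segments of length >= 11, the strict reading of
    "longer than 10 residues"; ``min_len=0`` keeps every run.
    """
    segs = [(s, e) for s, e in track.segments if e - s + 1 > min_len]
    return SegmentSet(kind=kind, segments=segs, protein_length=track.length)


def linker_lengths(domains: SegmentSet, protein_length: int | None = None) -> list[int]:
    """Inter-domain linker lengths: the gaps between consecutive domain
    segments.  Terminal tails are excluded; fewer than two domains give an
    empty list.  Adjacent domains contribute a zero-length linker."""
    segs = domains.segments
    return [segs[i + 1][0] - segs[i][1] - 1 for i in range(len(segs) - 1)]


def overlap_fraction(
    segsets: Sequence[SegmentSet], protein_length: int
) -> float:
    """Residue-level overlap between element kinds.

    Fraction of residues covered by >= 2 distinct kinds among residues covered
    by >= 1 kind; 0 when nothing is covered.
    """
    cover = np.zeros(protein_length, dtype=np.int64)
    for ss in segsets:
        bits = np.zeros(protein_length, dtype=np.int64)
        for s, e in ss.segments:
            bits[s - 1 : e] = 1
        cover += bits
    covered = int((cover >= 1).sum())
    if covered == 0:
        return 0.0
    return float((cover >= 2).sum()) / covered


# ---------------------------------------------------------------------------
# Element flags and co-occurrence categories
# ---------------------------------------------------------------------------

def consensus_idr_track(record: ProteinRecord) -> ResidueTrack:
    """Run the stringent disorder pipeline on a record's raw tracks.

    Missing predictor tracks read as all-zero (no prediction = no disorder).
    """
    n = record.length
    fib_bits = np.zeros(n, dtype=np.uint8)
    for name in TRACKS_CC + TRACKS_FIBRILLAR_EXTRA:
        fib_bits |= record.track_bits(name)
    bits = (
        record.track_bits(TRACKS_DISORDER[0])
        & record.track_bits(TRACKS_DISORDER[1])
        & (1 - fib_bits)
    )
    return ResidueTrack.from_bits("idr_consensus", bits)


def coiled_coil_track(record: ProteinRecord) -> ResidueTrack:
    """Permissive coiled-coil track: OR of the two predictor tracks."""
    bits = record.track_bits(TRACKS_CC[0]) | record.track_bits(TRACKS_CC[1])
    return ResidueTrack.from_bits("cc", bits)


def element_flags(
    record: ProteinRecord,
    min_len_idr: int = DEFAULT_MIN_LEN,
    min_len_cc: int = DEFAULT_MIN_LEN,
) -> ElementFlags:
    """Presence flags for IDR / CC / TM / DOMAIN.

    IDRs and coiled coils must exceed their length thresholds; a single
    transmembrane helix or domain segment of any length qualifies.
    """
    idr = extract_segments(consensus_idr_track(record), min_len_idr, "IDR")
    cc = extract_segments(coiled_coil_track(record), min_len_cc, "CC")
    tm = extract_segments(
        ResidueTrack.from_bits("tm", record.track_bits(TRACK_TM)), 0, "TM"
    )
    dom = extract_segments(
        ResidueTrack.from_bits("domain", record.track_bits(TRACK_DOMAIN)), 0, "DOMAIN"
    )
    return ElementFlags(
        has_idr=len(idr) > 0,
        has_cc=len(cc) > 0,
        has_tm=len(tm) > 0,
        has_domain=len(dom) > 0,
    )


def element_counts(
    record: ProteinRecord,
    min_len_idr: int = DEFAULT_MIN_LEN,
    min_len_cc: int = DEFAULT_MIN_LEN,
) -> dict[str, int]:
    """Qualifying-segment counts per element kind (IDR10/CC10/TMH/DOM)."""
    idr = extract_segments(consensus_idr_track(record), min_len_idr, "IDR")
    cc = extract_segments(coiled_coil_track(record), min_len_cc, "CC")
    tm = extract_segments(
        ResidueTrack.from_bits("tm", record.track_bits(TRACK_TM)), 0, "TM"
    )
    dom = extract_segments(
        ResidueTrack.from_bits("domain", record.track_bits(TRACK_DOMAIN)), 0, "DOMAIN"
    )
    return {"IDR10": len(idr), "CC10": len(cc), "TMH": len(tm), "DOM": len(dom)}


def cooccurrence_category(flags: ElementFlags) -> str:
    """Map an element-flag combination to exactly one of the 12 categories.

    The ten printed categories cover 10 of the 16 flag combinations; the
    residuals ``idr_other_combo`` (IDR+CC+TM, IDR+TM+DOMAIN) and ``none``
    make the partition exhaustive.
    """
    i, c, t, d = flags.has_idr, flags.has_cc, flags.has_tm, flags.has_domain
    n_ordered = sum((c, t, d))
    if not (i or c or t or d):
        return "none"
    if i and n_ordered == 0:
        return "idr_only"
    if not i:
        if n_ordered == 1:
            return "cc_only" if c else ("tm_only" if t else "domain_only")
        return "ordered_combo"
    # IDR plus at least one ordered element
    if i and c and t and d:
        return "all_four"
    if i and c and d:
        return "idr_cc_domain"
    if n_ordered == 1:
        return "idr_cc" if c else ("idr_tm" if t else "idr_domain")
    return "idr_other_combo"


@dataclass
class CooccurrenceTable:
    """Category counts and proportions over a protein set."""

    counts: dict[str, int]
    proportions: dict[str, float]
    set_size: int


def cooccurrence_table(
    records: Iterable[ProteinRecord],
    min_len_idr: int = DEFAULT_MIN_LEN,
    min_len_cc: int = DEFAULT_MIN_LEN,
    denominator: int | None = None,
) -> CooccurrenceTable:
    """Count proteins per element-combination category.

    ``denominator`` overrides the proportion denominator (e.g. to express a
    subset's counts against the exclusive proteome size); counts always sum to
    the number of records.
    """
    records = list(records)
    if not records:
        raise ValueError("empty record set")
    ctr = Counter(
        cooccurrence_category(element_flags(r, min_len_idr, min_len_cc))
        for r in records
    )
    n = denominator if denominator is not None else len(records)
    counts = {cat: ctr.get(cat, 0) for cat in CATEGORIES}
    return CooccurrenceTable(
        counts=counts,
        proportions={cat: counts[cat] / n for cat in CATEGORIES},
        set_size=len(records),
    )


def proportions_from_counts(
    counts: Mapping[str, int], set_size: int
) -> dict[str, float]:
    """Category proportions from pre-computed counts and a set size."""
    return {cat: cnt / set_size for cat, cnt in counts.items()}
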