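"""Data model and file I/O for protein annotation pipelines.

Proteins carry per-residue binary annotation tracks (disorder, coiled coil,
transmembrane, domain, ...) and per-protein counts (phosphorylation sites,
interaction degree, ...).  All residue coordinates are 1-based with inclusive
segment ends, the UniProt convention; tracks are stored sparsely as merged
segment lists and expanded to bit vectors on demand.

Formats
-------
* FASTA for sequences (via Bio.SeqIO).
* Annotation TSV: one row per protein, columns ``id``, ``track:<name>``
  (comma-separated ``start-end`` segments) and ``count:<name>`` (integers).
* Set membership: two-column TSV (``set-name<TAB>id``) or a JSON object
  mapping set name to an id list.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO

logger = logging.getLogger("dpiscope")

#: Canonical protein-set names recognised throughout the pipeline.
CANONICAL_SETS = (
    "proteome",
    "synaptome",
    "psd",
    "psc",
    "immunome",
    "nucleus",
    "histone_methylases",
)

#: Expected nesting among the canonical synaptic sets (outer, inner) pairs.
CANONICAL_NESTING = (
    ("proteome", "synaptome"),
    ("synaptome", "psd"),
    ("psd", "psc"),
)

#: Per-protein count column names.
COUNT_NAMES = (
    "phospho",
    "ubiq",
    "methyl",
    "acetyl",
    "elm_ligdoc",
    "isoforms",
    "ppi_degree",
)

STANDARD_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"
AMBIGUOUS_RESIDUES = set("XBZU")


class FormatError(ValueError):
    """Raised for malformed input files, naming the offending entry."""


class BoundsError(ValueError):
    """Raised when a segment exceeds its protein's length."""


def merge_segments(segments: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Canonicalize a list of 1-based inclusive intervals: sort and merge
    overlapping or adjacent-overlapping ones (``2-4`` and ``4-6`` become ``2-6``)."""
    segs = sorted((int(s), int(e)) for s, e in segments)
    merged: list[tuple[int, int]] = []
    for s, e in segs:
        if s > e:
            raise ValueError(f"segment start {s} > end {e}")
        if merged and s <= merged[-1][1] + 0:  # overlap (not mere adjacency)
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


@dataclass
class ResidueTrack:
    """A named binary annotation over residue positions.

    Stored sparsely as merged 1-based inclusive segments; ``bits`` expands to a
    0/1 vector of the owning protein's length.  Equality is positional: two
    tracks are equal iff their expanded bit vectors are.
    """

    name: str
    length: int
    segments: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.segments = merge_segments(self.segments)
        for s, e in self.segments:
            if s < 1 or e > self.length:
                raise BoundsError(
                    f"track {self.name!r}: segment {s}-{e} outside 1..{self.length}"
                )

    @classmethod
    def from_bits(cls, name: str, bits: Sequence[int] | np.ndarray) -> "ResidueTrack":
        arr = np.asarray(bits)
        if not np.isin(arr, (0, 1)).all():
            raise ValueError(f"track {name!r}: bits must be 0/1")
        segs = []
        pos = np.flatnonzero(arr)
        if pos.size:
            breaks = np.flatnonzero(np.diff(pos) > 1)
            starts = np.r_[pos[0], pos[breaks + 1]]
            ends = np.r_[pos[breaks], pos[-1]]
            segs = [(int(s) + 1, int(e) + 1) for s, e in zip(starts, ends)]
        return cls(name=name, length=len(arr), segments=segs)

    @property
    def bits(self) -> np.ndarray:
        out = np.zeros(self.length, dtype=np.uint8)
        for s, e in self.segments:
            out[s - 1 : e] = 1
        return out

    def count(self) -> int:
        """Number of annotated residues (equals the merged segment length sum)."""
        return sum(e - s + 1 for s, e in self.segments)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ResidueTrack):
            return NotImplemented
        return self.length == other.length and np.array_equal(self.bits, other.bits)


@dataclass
class ProteinRecord:
    """One protein: accession, length, optional sequence, tracks and counts."""

    id: str
    length: int
    sequence: str | None = None
    tracks: dict[str, ResidueTrack] = field(default_factory=dict)
    counts: dict[str, int] = field(default_factory=dict)
    has_ambiguous: bool = False

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"{self.id}: length must be positive")
        if self.sequence is not None and len(self.sequence) != self.length:
            raise ValueError(
                f"{self.id}: sequence length {len(self.sequence)} != {self.length}"
            )
        for name, track in self.tracks.items():
            if track.length != self.length:
                raise ValueError(f"{self.id}: track {name!r} length mismatch")
        for name, c in self.counts.items():
            if c < 0:
                raise ValueError(f"{self.id}: count {name!r} is negative")

    def track_bits(self, name: str) -> np.ndarray:
        """Bit vector for ``name``; a missing track reads as all-zero."""
        if name in self.tracks:
            return self.tracks[name].bits
        return np.zeros(self.length, dtype=np.uint8)


@dataclass
class ProteinSetCollection:
    """Named protein-id sets over a universe (the proteome)."""

    universe: set[str]
    sets: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            stray = members - self.universe
            if stray:
                raise ValueError(f"set {name!r} has ids outside universe: {sorted(stray)[:5]}")

    def exclusive_set(self, name: str) -> set[str]:
        """Universe minus the named set, e.g. the PSD-exclusive proteome."""
        if name not in self.sets:
            raise KeyError(f"unknown set {name!r}")
        return self.universe - self.sets[name]

    def check_nesting(self) -> dict[tuple[str, str], set[str]]:
        """Violators of the canonical proteome ⊇ synaptome ⊇ psd ⊇ psc nesting."""
        violations: dict[tuple[str, str], set[str]] = {}
        for outer, inner in CANONICAL_NESTING:
            if outer in self.sets and inner in self.sets:
                stray = self.sets[inner] - self.sets[outer]
                if stray:
                    violations[(outer, inner)] = stray
        return violations


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read protein records from FASTA.

    Unknown residues (X/B/Z/U) are retained in the sequence but flag the record
    via ``has_ambiguous``.  An empty file yields an empty list; an entry with an
    empty sequence raises :class:`FormatError` naming it.
    """
    path = Path(path)
    records: list[ProteinRecord] = []
    for entry in SeqIO.parse(str(path), "fasta"):
        seq = str(entry.seq).upper()
        if not entry.id:
            raise FormatError(f"{path}: entry with empty header")
        if not seq:
            raise FormatError(f"{path}: entry {entry.id!r} has an empty sequence")
        records.append(
            ProteinRecord(
                id=entry.id,
                length=len(seq),
                sequence=seq,
                has_ambiguous=bool(set(seq) & AMBIGUOUS_RESIDUES),
            )
        )
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            if rec.sequence is None:
                raise ValueError(f"{rec.id}: no sequence to write")
            fh.write(f">{rec.id}\n")
            for i in range(0, rec.length, 60):
                fh.write(rec.sequence[i : i + 60] + "\n")


# ---------------------------------------------------------------------------
# Annotation tables
# ---------------------------------------------------------------------------

def _parse_segments(cell: str) -> list[tuple[int, int]]:
    segs = []
    cell = cell.strip()
    if not cell or cell == ".":
        return segs
    for part in cell.split(","):
        try:
            s, e = part.split("-")
            segs.append((int(s), int(e)))
        except ValueError as exc:
            raise FormatError(f"malformed segment {part!r}") from exc
    return segs


def read_annotations(
    path: str | Path, records: Sequence[ProteinRecord]
) -> list[ProteinRecord]:
    """Attach tracks and counts from an annotation TSV to existing records.

    Rows are matched by id; a row whose id is not among ``records`` raises
    :class:`FormatError`.  Overlapping segments within one track are merged
    silently; a segment end beyond the protein length raises
    :class:`BoundsError`.  Proteins without a row keep empty tracks and zero
    counts (a warning is logged).
    """
    path = Path(path)
    by_id = {r.id: r for r in records}
    seen: set[str] = set()
    with open(path) as fh:
        header: list[str] | None = None
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = fields
                if header[0] != "id":
                    raise FormatError(f"{path}: first column must be 'id'")
                continue
            row = dict(zip(header, fields))
            pid = row["id"]
            if pid not in by_id:
                raise FormatError(f"{path}: row for unknown protein id {pid!r}")
            rec = by_id[pid]
            seen.add(pid)
            for col, cell in row.items():
                if col.startswith("track:"):
                    name = col[len("track:") :]
                    segs = _parse_segments(cell)
                    for s, e in segs:
                        if e > rec.length or s < 1:
                            raise BoundsError(
                                f"{pid}: segment {s}-{e} in track {name!r} "
                                f"exceeds length {rec.length}"
                            )
                    rec.tracks[name] = ResidueTrack(name, rec.length, segs)
                elif col.startswith("count:"):
                    name = col[len("count:") :]
                    rec.counts[name] = int(cell) if cell not in ("", ".") else 0
    missing = set(by_id) - seen
    if missing:
        logger.warning(
            "%d proteins had no annotation row (empty tracks, zero counts)",
            len(missing),
        )
    return list(records)


def write_annotations(
    records: Iterable[ProteinRecord], path: str | Path, comment: str | None = None
) -> None:
    """Write an annotation TSV in canonical form (sorted, merged segments).

    Reading the output back reproduces the same tracks and counts.
    """
    records = list(records)
    track_names = sorted({n for r in records for n in r.tracks})
    count_names = sorted({n for r in records for n in r.counts})
    with open(path, "w") as fh:
        fh.write("# coordinates: 1-based, inclusive ends\n")
        if comment:
            fh.write(f"# {comment}\n")
        cols = ["id"] + [f"track:{n}" for n in track_names] + [
            f"count:{n}" for n in count_names
        ]
        fh.write("\t".join(cols) + "\n")
        for rec in records:
            cells = [rec.id]
            for n in track_names:
                segs = rec.tracks[n].segments if n in rec.tracks else []
                cells.append(",".join(f"{s}-{e}" for s, e in segs) or ".")
            for n in count_names:
                cells.append(str(rec.counts.get(n, 0)))
            fh.write("\t".join(cells) + "\n")


# ---------------------------------------------------------------------------
# Protein sets
# ---------------------------------------------------------------------------

def read_sets(path: str | Path, universe: set[str]) -> ProteinSetCollection:
    """Read set membership from two-column TSV or JSON.

    Ids outside the universe are excluded with a warning rather than raising:
    the source localization databases are noisy and occasionally list obsolete
    accessions.  Canonical-nesting violations are reported as warnings listing
    the violators.
    """
    path = Path(path)
    raw: dict[str, list[str]] = {}
    if path.suffix == ".json":
        raw = json.loads(path.read_text())
    else:
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                name, pid = line.split("\t")
                raw.setdefault(name, []).append(pid)
    sets: dict[str, set[str]] = {}
    for name, ids in raw.items():
        members = set(ids)
        stray = members - universe
        if stray:
            warnings.warn(
                f"set {name!r}: {len(stray)} ids outside universe excluded "
                f"(e.g. {sorted(stray)[:3]})",
                stacklevel=2,
            )
            members &= universe
        sets[name] = members
    coll = ProteinSetCollection(universe=universe, sets=sets)
    for (outer, inner), stray in coll.check_nesting().items():
        warnings.warn(
            f"nesting violation: {len(stray)} members of {inner!r} missing from "
            f"{outer!r} (e.g. {sorted(stray)[:3]})",
            stacklevel=2,
        )
    return coll


def write_sets(collection: ProteinSetCollection, path: str | Path) -> None:
    path = Path(path)
    if path.suffix == ".json":
        path.write_text(
            json.dumps({k: sorted(v) for k, v in collection.sets.items()}, indent=1)
        )
    else:
        with open(path, "w") as fh:
            for name in sorted(collection.sets):
                for pid in sorted(collection.sets[name]):
                    fh.write(f"{name}\t{pid}\n")


def exclusive_set(collection: ProteinSetCollection, name: str) -> set[str]:
    """Module-level alias for :meth:`ProteinSetCollection.exclusive_set`."""
    return collection.exclusive_set(name)
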