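"""Sequence-derived features: physicochemical group composition, amino-acid
scale averaging, and clustering-based scale selection.

Residues are partitioned into eight physicochemical groups (hydrophobic
A/I/L/M/V, aromatic F/W/Y, polar N/Q/S/T, positively charged H/K/R, negatively
charged D/E, rigid P, flexible G, covalently interacting C).  Amino-acid
scales — 20-value property tables in the AAIndex tradition — are averaged over
the sequence, and a large scale collection can be reduced to a handful of
representatives by Ward-linkage hierarchical clustering with elbow-based
choice of the cluster count, one randomly chosen representative per cluster.

Nonstandard letters (X/B/Z/U/...) are excluded from both group and scale
statistics; they are never imputed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage

from .core_io import STANDARD_RESIDUES

logger = logging.getLogger("dpiscope")

#: Default physicochemical grouping of the 20 standard residues.
DEFAULT_GROUPS: dict[str, frozenset[str]] = {
    "hydrophobic": frozenset("AILMV"),
    "aromatic": frozenset("FWY"),
    "polar": frozenset("NQST"),
    "positive": frozenset("HKR"),
    "negative": frozenset("DE"),
    "rigid": frozenset("P"),
    "flexible": frozenset("G"),
    "covalent": frozenset("C"),
}


class UndefinedCompositionError(ValueError):
    """Sequence contains no standard residues."""


@dataclass(frozen=True)
class GroupScheme:
    """Disjoint residue groups covering the 20 standard residues exactly."""

    groups: dict[str, frozenset[str]]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for name, letters in self.groups.items():
            if seen & letters:
                raise ValueError(f"group {name!r} overlaps another group")
            seen |= letters
        if seen != set(STANDARD_RESIDUES):
            raise ValueError("groups must cover the 20 standard residues exactly")


DEFAULT_SCHEME = GroupScheme(DEFAULT_GROUPS)


@dataclass(frozen=True)
class AminoAcidScale:
    """A named 20-value residue property table."""

    id: str
    values: dict[str, float]

    def __post_init__(self) -> None:
        if set(self.values) != set(STANDARD_RESIDUES):
            raise ValueError(f"scale {self.id!r} must define exactly 20 residues")

    def as_array(self) -> np.ndarray:
        return np.array([self.values[a] for a in STANDARD_RESIDUES], dtype=float)


def group_composition(
    sequence: str, scheme: GroupScheme = DEFAULT_SCHEME
) -> dict[str, float]:
    """Fraction of residues per physicochemical group.

    Fractions are computed over standard residues only, so they sum to 1;
    nonstandard letters count in neither numerator nor denominator.
    """
    counts = {name: 0 for name in scheme.groups}
    letter_to_group = {a: g for g, letters in scheme.groups.items() for a in letters}
    n = 0
    for a in sequence.upper():
        g = letter_to_group.get(a)
        if g is not None:
            counts[g] += 1
            n += 1
    if n == 0:
        raise UndefinedCompositionError("no standard residues in sequence")
    return {name: c / n for name, c in counts.items()}


def scale_mean(sequence: str, scale: AminoAcidScale) -> float:
    """Arithmetic mean of per-residue scale values; nonstandard letters skipped."""
    vals = [scale.values[a] for a in sequence.upper() if a in scale.values]
    if not vals:
        raise UndefinedCompositionError("no standard residues in sequence")
    return float(np.mean(vals))


# ---------------------------------------------------------------------------
# Scale tables
# ---------------------------------------------------------------------------

def read_scales(path: str | Path) -> list[AminoAcidScale]:
    """Read scale tables from TSV: header ``id`` + the 20 residue letters."""
    scales = []
    with open(path) as fh:
        header: list[str] | None = None
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = fields
                continue
            row = dict(zip(header, fields))
            scales.append(
                AminoAcidScale(
                    id=row["id"],
                    values={a: float(row[a]) for a in STANDARD_RESIDUES},
                )
            )
    return scales


def default_scales() -> list[AminoAcidScale]:
    """The packaged five-scale fixture (synthetic stand-in tables).

    Five synthetic property tables spanning distinct physicochemical axes —
    hydropathy, net charge, side-chain volume, backbone flexibility and
    aromaticity — so that prediction-only mode works without an external scale
    database.  They are constructed stand-ins, not copies of any published
    scale collection; pass your own TSV to :func:`read_scales` to use real
    AAIndex tables.
    """
    pkg = resources.files("dpiscope.data")
    with resources.as_file(pkg / "default_scales_synthetic.tsv") as p:
        return read_scales(p)


# ---------------------------------------------------------------------------
# Scale clustering and representative selection
# ---------------------------------------------------------------------------

def _standardize(matrix: np.ndarray) -> np.ndarray:
    mu = matrix.mean(axis=1, keepdims=True)
    sd = matrix.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return (matrix - mu) / sd

def cluster_scales(
    scales: list[AminoAcidScale], k_range: range
) -> dict[int, dict]:
    """Ward-linkage hierarchical clustering of standardized scales.

    Each scale's 20 values are standardized (zero mean, unit variance) before
    Euclidean distances are taken, so clustering reflects the shape of a scale
    rather than its units.  Returns, for every k in ``k_range``, the partition
    (cluster label -> scale ids) and the total within-cluster sum of squares.
    Use :func:`elbow_k` on the dispersions to pick k.
    """
    if max(k_range) > len(scales):
        raise ValueError(f"k={max(k_range)} exceeds number of scales ({len(scales)})")
    X = _standardize(np.vstack([s.as_array() for s in scales]))
    Z = linkage(X, method="ward")
    out: dict[int, dict] = {}
    for k in k_range:
        labels = fcluster(Z, t=k, criterion="maxclust")
        partition: dict[int, list[str]] = {}
        wss = 0.0
        for lab in np.unique(labels):
            idx = np.flatnonzero(labels == lab)
            partition[int(lab)] = [scales[i].id for i in idx]
            centroid = X[idx].mean(axis=0)
            wss += float(((X[idx] - centroid) ** 2).sum())
        out[k] = {"partition": partition, "dispersion": wss}
    return out


def elbow_k(dispersions: dict[int, float]) -> int:
    """Elbow choice of k: argmax of the second forward difference of the
    within-cluster dispersion curve over k (interior points only).

    With fewer than three k values the smallest k is returned.
    """
    ks = sorted(dispersions)
    if len(ks) < 3:
        return ks[0]
    best_k, best_curv = ks[1], -np.inf
    for i in range(1, len(ks) - 1):
        curv = (
            dispersions[ks[i - 1]] - 2 * dispersions[ks[i]] + dispersions[ks[i + 1]]
        )
        if curv > best_curv:
            best_curv, best_k = curv, ks[i]
    return best_k


def select_representatives(
    partition: dict[int, list[str]], seed: int
) -> list[str]:
    """One uniformly chosen scale id per cluster; deterministic given seed.

    Clusters are visited in sorted label order, so singleton clusters yield
    their sole member in cluster order.
    """
    rng = np.random.default_rng(seed)
    chosen = []
    for lab in sorted(partition):
        members = partition[lab]
        if not members:
            raise ValueError(f"cluster {lab} is empty")
        chosen.append(members[int(rng.integers(len(members)))])
    return chosen
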