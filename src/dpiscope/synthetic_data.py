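"""Synthetic proteome generator with the statistical structure the analysis
assumes.

The generator emulates a human-proteome-scale study without any database
downloads: nested protein sets (proteome ⊇ synaptome ⊇ PSD ⊇ PSC, default
sizes 21,766 / 1,891 / 1,761 / 51, scalable by a size factor) plus three
disjoint control sets (immunome, nucleus, histone methylases).  Per protein it
draws:

* a log-normal length with set-specific means (proteome 524, PSD 705,
  PSC 970 residues);
* overdispersed negative-binomial feature counts (domains, long coiled coils,
  long IDRs, TM helices, PTM sites, linear motifs, isoforms, interaction
  degree) whose set-specific means are the proteome baseline times explicit
  per-set effect multipliers;
* residue composition summaries (group fractions, scale means) from
  set-specific amino-acid frequencies (PSD-like: ~28% charged, ~2% Cys,
  ~5% Pro; proteome-like: ~25% / ~3% / ~6%);
* optionally, per-residue tracks realising the counts as placed segments, and
  amino-acid sequences (with plantable homolog families for redundancy-filter
  tests).

A Gaussian-copula step can regenerate the interaction degree so that its
Spearman correlation with each protein's DPI score hits a configured target.
All outputs are pure functions of (config, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import (
    STANDARD_RESIDUES,
    ProteinRecord,
    ProteinSetCollection,
    ResidueTrack,
)
from .dpi_stats import dpi_column
from .sequence_features import DEFAULT_SCHEME, default_scales

#: Count features drawn per protein.
COUNT_FEATURES = (
    "DOM", "CC10", "IDR10", "TMH", "Ph", "Ub", "ELM",
    "LCR", "methyl", "acetyl", "isoforms", "ppi_degree", "anchor",
)

#: Proteome-baseline negative-binomial means per count feature.
BASE_COUNT_MEANS = {
    "DOM": 1.3, "CC10": 0.3, "IDR10": 1.0, "TMH": 0.8,
    "Ph": 5.0, "Ub": 2.0, "ELM": 3.0, "LCR": 1.0,
    "methyl": 0.4, "acetyl": 0.6, "isoforms": 1.5,
    "ppi_degree": 5.0, "anchor": 1.0,
}

#: Per-set mean multipliers relative to the proteome baseline.  Directions
#: mirror the study system: PSD-like sets gain coiled coils, domains, PTM
#: sites, interactions and isoforms, lose TM helices; disorder is enriched
#: only in scaffold-like (PSC) sets; the controls are a globular multidomain
#: set, a high-interaction nuclear set and a disorder-rich enzyme family.
EFFECT_SIZES = {
    "psd": {
        "DOM": 1.5, "CC10": 2.2, "IDR10": 1.0, "TMH": 0.6, "Ph": 2.5,
        "Ub": 2.0, "ELM": 1.5, "LCR": 1.0, "methyl": 1.3, "acetyl": 1.3,
        "isoforms": 1.5, "ppi_degree": 2.0, "anchor": 0.9,
    },
    "psc": {
        "DOM": 1.8, "CC10": 3.0, "IDR10": 1.8, "TMH": 0.4, "Ph": 2.5,
        "Ub": 2.0, "ELM": 1.8, "LCR": 1.2, "methyl": 1.0, "acetyl": 1.0,
        "isoforms": 1.6, "ppi_degree": 2.2, "anchor": 1.5,
    },
    "immunome": {"DOM": 1.8, "IDR10": 0.7, "CC10": 0.8, "TMH": 1.2},
    "nucleus": {"ppi_degree": 1.8, "IDR10": 1.3, "Ph": 1.5},
    "histone_methylases": {"IDR10": 2.0, "DOM": 1.2, "ppi_degree": 1.2},
}

#: Set-specific residue frequency targets: (charged, cysteine, proline).
COMPOSITION_TARGETS = {
    "proteome": (0.25, 0.03, 0.06),
    "psd": (0.28, 0.02, 0.05),
    "psc": (0.28, 0.02, 0.06),
}

#: Human-like baseline amino-acid frequencies (fractions, sum 1).
_BASE_FREQS = {
    "A": 0.070, "R": 0.056, "N": 0.036, "D": 0.047, "C": 0.023,
    "Q": 0.048, "E": 0.071, "G": 0.066, "H": 0.026, "I": 0.043,
    "L": 0.100, "K": 0.057, "M": 0.021, "F": 0.037, "P": 0.063,
    "S": 0.083, "T": 0.053, "W": 0.012, "Y": 0.027, "V": 0.061,
}

CHARGED = set("HKRDE")

#: Mean placed-segment length per kind, used for feasibility budgeting.
SEGMENT_LENGTH_RANGES = {
    "DOM": (40, 120), "TMH": (17, 26), "CC10": (12, 30),
    "IDR10": (11, 40), "LCR": (8, 25),
}

STRATA = (
    "proteome_only", "synaptome_only", "psd_only", "psc",
    "immunome", "nucleus", "histone_methylases",
)


class ConfigError(ValueError):
    """Invalid generator configuration; message lists offending fields."""


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic proteome.

    Defaults mirror the real study's set sizes and headline sequence
    statistics; ``size_factor`` scales every set (PSC never below 10) for
    desk-scale runs.  ``effect_scale`` exponentiates every effect multiplier
    (0 gives a null proteome with no set differences, 1 the default effects,
    >1 strongly separated sets).
    """

    n_per_set: dict[str, int] = field(
        default_factory=lambda: {
            "proteome": 21766, "synaptome": 1891, "psd": 1761, "psc": 51,
            "immunome": 834, "nucleus": 180, "histone_methylases": 52,
        }
    )
    size_factor: float = 1.0
    length_means: dict[str, float] = field(
        default_factory=lambda: {"proteome": 524.0, "psd": 705.0, "psc": 970.0}
    )
    length_sigma: float = 0.7
    base_count_means: dict[str, float] = field(
        default_factory=lambda: dict(BASE_COUNT_MEANS)
    )
    effect_sizes: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in EFFECT_SIZES.items()}
    )
    effect_scale: float = 1.0
    dispersion: float = 2.0
    rho_dpi_ppi: float | None = 0.35
    disorder_agreement: float = 1.0
    cross_overlap_rate: float = 0.005
    footprint_budget: float = 0.75

    def validate(self) -> None:
        bad = []
        for name, n in self.scaled_sizes().items():
            if n < 10:
                bad.append(f"n_per_set[{name}]={n} < 10 after scaling")
        for set_name, effects in self.effect_sizes.items():
            for feat, m in effects.items():
                if m <= 0:
                    bad.append(f"effect_sizes[{set_name}][{feat}]={m} <= 0")
        if self.rho_dpi_ppi is not None and abs(self.rho_dpi_ppi) > 1:
            bad.append(f"rho_dpi_ppi={self.rho_dpi_ppi} outside [-1, 1]")
        if not 0 <= self.disorder_agreement <= 1:
            bad.append(f"disorder_agreement={self.disorder_agreement}")
        if self.dispersion <= 0:
            bad.append(f"dispersion={self.dispersion} <= 0")
        if bad:
            raise ConfigError("; ".join(bad))

    def scaled_sizes(self) -> dict[str, int]:
        return {
            name: max(10, int(round(n * self.size_factor)))
            for name, n in self.n_per_set.items()
        }


# ---------------------------------------------------------------------------
# Composition helpers
# ---------------------------------------------------------------------------

def composition_vector(
    charged: float, cys: float, pro: float
) -> np.ndarray:
    """A 20-letter frequency vector (ordered as STANDARD_RESIDUES) hitting the
    requested charged / cysteine / proline fractions, other residues scaled
    from human-like baseline frequencies."""
    freqs = dict(_BASE_FREQS)
    base_charged = sum(freqs[a] for a in CHARGED)
    for a in CHARGED:
        freqs[a] *= charged / base_charged
    freqs["C"] = cys
    freqs["P"] = pro
    rest = [a for a in freqs if a not in CHARGED and a not in ("C", "P")]
    remaining = 1.0 - charged - cys - pro
    base_rest = sum(freqs[a] for a in rest)
    for a in rest:
        freqs[a] *= remaining / base_rest
    vec = np.array([freqs[a] for a in STANDARD_RESIDUES])
    if not math.isclose(vec.sum(), 1.0, abs_tol=1e-9):
        raise ConfigError(f"composition sums to {vec.sum()}, not 1")
    return vec


def _stratum_composition(stratum: str, effect_scale: float = 1.0) -> np.ndarray:
    if stratum in ("psd_only", "psc"):
        key = "psc" if stratum == "psc" else "psd"
    else:
        key = "proteome"
    base = COMPOSITION_TARGETS["proteome"]
    tgt = COMPOSITION_TARGETS[key]
    mixed = tuple(b + effect_scale * (t - b) for b, t in zip(base, tgt))
    return composition_vector(*mixed)


def _stratum_length_mean(stratum: str, cfg: GeneratorConfig) -> float:
    base = cfg.length_means["proteome"]
    if stratum == "psc":
        tgt = cfg.length_means["psc"]
    elif stratum in ("psd_only", "synaptome_only"):
        tgt = cfg.length_means["psd"]
    else:
        tgt = base
    return base * (tgt / base) ** cfg.effect_scale


def _stratum_count_means(stratum: str, cfg: GeneratorConfig) -> dict[str, float]:
    base = cfg.base_count_means
    if stratum == "proteome_only":
        mult = {}
    elif stratum == "synaptome_only":
        # synaptic but non-PSD proteins: halfway to PSD effects in log space
        mult = {k: v**0.5 for k, v in cfg.effect_sizes["psd"].items()}
    elif stratum == "psd_only":
        mult = cfg.effect_sizes["psd"]
    elif stratum == "psc":
        mult = cfg.effect_sizes["psc"]
    else:
        mult = cfg.effect_sizes.get(stratum, {})
    return {
        f: base[f] * (mult.get(f, 1.0) ** cfg.effect_scale) for f in COUNT_FEATURES
    }


# ---------------------------------------------------------------------------
# Feature-table generation
# ---------------------------------------------------------------------------

def _nb_draw(rng: np.random.Generator, mean: float, k: float, size: int) -> np.ndarray:
    """Negative binomial with mean ``mean`` and dispersion ``k``
    (variance = mean + mean^2 / k)."""
    if mean <= 0:
        return np.zeros(size, dtype=int)
    p = k / (k + mean)
    return rng.negative_binomial(k, p, size=size)


def _segment_footprint(counts: dict[str, int]) -> float:
    mean_len = {k: (lo + hi) / 2 for k, (lo, hi) in SEGMENT_LENGTH_RANGES.items()}
    return sum(counts.get(k, 0) * (mean_len[k] + 1) for k in SEGMENT_LENGTH_RANGES)


def generate_feature_table(
    config: GeneratorConfig, seed: int = 0
) -> tuple[pd.DataFrame, ProteinSetCollection]:
    """Draw the per-protein feature table and the nested set collection.

    The returned frame is indexed by protein id with columns: ``length``, the
    count features, group fractions, scale means, ``stratum`` and ``dpi``
    (log1p convention).  Deterministic per (config, seed).
    """
    config.validate()
    rng = np.random.default_rng(seed)
    sizes = config.scaled_sizes()
    n_total = sizes["proteome"] + sum(
        sizes.get(s, 0) for s in ("immunome", "nucleus", "histone_methylases")
    )

    # assign strata; synaptic sets nest inside the proteome, controls outside it
    strata: list[str] = []
    strata += ["psc"] * sizes["psc"]
    strata += ["psd_only"] * (sizes["psd"] - sizes["psc"])
    strata += ["synaptome_only"] * (sizes["synaptome"] - sizes["psd"])
    strata += ["proteome_only"] * (sizes["proteome"] - sizes["synaptome"])
    for ctrl in ("immunome", "nucleus", "histone_methylases"):
        strata += [ctrl] * sizes.get(ctrl, 0)
    ids = [f"SYN{i:06d}" for i in range(len(strata))]

    frames = []
    scales = default_scales()
    group_names = list(DEFAULT_SCHEME.groups)
    letter_groups = np.array(
        [
            [1.0 if a in DEFAULT_SCHEME.groups[g] else 0.0 for a in STANDARD_RESIDUES]
            for g in group_names
        ]
    )  # (n_groups, 20)
    scale_mat = np.vstack([s.as_array() for s in scales])  # (n_scales, 20)

    strata_arr = np.array(strata)
    table = pd.DataFrame(index=pd.Index(ids, name="id"))
    table["stratum"] = strata_arr
    table["length"] = 0
    for f in COUNT_FEATURES:
        table[f] = 0

    for stratum in STRATA:
        mask = strata_arr == stratum
        m = int(mask.sum())
        if m == 0:
            continue
        mean_len = _stratum_length_mean(stratum, config)
        mu = math.log(mean_len) - config.length_sigma**2 / 2
        lengths = np.maximum(
            30, rng.lognormal(mu, config.length_sigma, size=m).astype(int)
        )
        table.loc[mask, "length"] = lengths
        means = _stratum_count_means(stratum, config)
        for f in COUNT_FEATURES:
            table.loc[mask, f] = _nb_draw(rng, means[f], config.dispersion, m)

    # cap segment-bearing counts so tracks remain placeable within the length
    budget = config.footprint_budget * table["length"].to_numpy()
    seg_feats = list(SEGMENT_LENGTH_RANGES)
    counts_arr = table[seg_feats].to_numpy().astype(int)
    mean_len = np.array(
        [(lo + hi) / 2 + 1 for lo, hi in SEGMENT_LENGTH_RANGES.values()]
    )
    footprint = counts_arr @ mean_len
    for i in np.flatnonzero(footprint > budget):
        c = counts_arr[i].copy()
        while (c @ mean_len) > budget[i] and c.sum() > 0:
            c[int(np.argmax(c * mean_len))] -= 1
        counts_arr[i] = c
    table[seg_feats] = counts_arr

    # sequence-composition summaries from multinomial residue counts
    comp = np.zeros((len(table), 20))
    for stratum in STRATA:
        mask = strata_arr == stratum
        if not mask.any():
            continue
        p = _stratum_composition(stratum, config.effect_scale)
        lens = table.loc[mask, "length"].to_numpy()
        draws = np.stack([rng.multinomial(n, p) for n in lens])
        comp[mask] = draws / lens[:, None]
    for gi, g in enumerate(group_names):
        table[g] = comp @ letter_groups[gi]
    for si, s in enumerate(scales):
        table[f"scale_{s.id.removesuffix('_syn')}"] = comp @ scale_mat[si]

    table["dpi"] = dpi_column(table)
    if config.rho_dpi_ppi is not None:
        table = plant_dpi_ppi_correlation(
            table, config.rho_dpi_ppi, seed=int(rng.integers(2**31 - 1)),
            group_col="stratum",
        )

    proteome_ids = set(table.index[np.isin(strata_arr, STRATA[:4])])
    universe = set(table.index)
    sets = {
        "proteome": proteome_ids,
        "synaptome": set(
            table.index[np.isin(strata_arr, ("psc", "psd_only", "synaptome_only"))]
        ),
        "psd": set(table.index[np.isin(strata_arr, ("psc", "psd_only"))]),
        "psc": set(table.index[strata_arr == "psc"]),
        "immunome": set(table.index[strata_arr == "immunome"]),
        "nucleus": set(table.index[strata_arr == "nucleus"]),
        "histone_methylases": set(table.index[strata_arr == "histone_methylases"]),
    }
    collection = ProteinSetCollection(universe=universe, sets=sets)
    return table, collection


# ---------------------------------------------------------------------------
# DPI–PPI copula coupling
# ---------------------------------------------------------------------------

def plant_dpi_ppi_correlation(
    table: pd.DataFrame,
    rho: float,
    seed: int = 0,
    group_col: str | None = None,
) -> pd.DataFrame:
    """Reassign ``ppi_degree`` so Spearman(DPI, PPI) targets ``rho``.

    A Gaussian copula couples normal scores of the DPI ranks to a latent
    variable; the existing ``ppi_degree`` values are reassigned (within each
    ``group_col`` stratum, preserving every stratum's marginal exactly) by
    matching ranks of the latent variable.  The Pearson parameter is chosen as
    2·sin(π·rho/6) so the induced Spearman correlation is ``rho``.
    """
    if abs(rho) > 1:
        raise ValueError("|rho| must be <= 1")
    out = table.copy()
    rng = np.random.default_rng(seed)
    r_p = 2 * math.sin(math.pi * rho / 6)
    groups = (
        out.groupby(group_col, sort=False).indices.values()
        if group_col is not None
        else [np.arange(len(out))]
    )
    d_all = out["dpi"].to_numpy(dtype=float)
    v_all = out["ppi_degree"].to_numpy()
    new = v_all.copy()
    for idx in groups:
        idx = np.asarray(idx)
        n = idx.size
        d = d_all[idx]
        order = np.lexsort((rng.random(n), d))  # ranks with random tie-break
        ranks = np.empty(n, dtype=int)
        ranks[order] = np.arange(n)
        z_d = stats.norm.ppf((ranks + 0.5) / n)
        z = r_p * z_d + math.sqrt(max(0.0, 1 - r_p**2)) * rng.standard_normal(n)
        z_rank = np.empty(n, dtype=int)
        z_rank[np.argsort(z, kind="stable")] = np.arange(n)
        new[idx] = np.sort(v_all[idx])[z_rank]
    out["ppi_degree"] = new
    out["dpi"] = dpi_column(out)
    return out


# ---------------------------------------------------------------------------
# Track generation
# ---------------------------------------------------------------------------

_KIND_TO_TRACKS = {
    "DOM": ("domain",),
    "TMH": ("tm",),
    "CC10": ("cc_coils", "cc_paircoil"),
    "LCR": ("lcr",),
}


class PackingError(ValueError):
    """Requested segments cannot be placed within the protein length."""


def _place_segments(
    occupied: np.ndarray,
    count: int,
    length_range: tuple[int, int],
    rng: np.random.Generator,
    ignore_occupancy_p: float = 0.0,
    own: np.ndarray | None = None,
) -> list[tuple[int, int]]:
    """Place ``count`` non-overlapping segments (1-based inclusive) into free
    space, with a 1-residue guard so same-kind segments never merge."""
    n = occupied.size
    segs = []
    for _ in range(count):
        lo, hi = length_range
        seg_len = int(rng.integers(lo, hi + 1))
        placed = False
        for attempt_len in range(seg_len, lo - 1, -1):
            blocked = occupied
            if ignore_occupancy_p > 0 and rng.random() < ignore_occupancy_p:
                blocked = own if own is not None else np.zeros(n, dtype=bool)
            csum = np.concatenate([[0], np.cumsum(blocked)])
            window = csum[attempt_len:] - csum[:-attempt_len]
            starts = np.flatnonzero(window == 0)
            if starts.size:
                s0 = int(starts[int(rng.integers(starts.size))])
                segs.append((s0 + 1, s0 + attempt_len))
                lo_g = max(0, s0 - 1)
                hi_g = min(n, s0 + attempt_len + 1)
                occupied[lo_g:hi_g] = True
                if own is not None:
                    own[lo_g:hi_g] = True
                placed = True
                break
        if not placed:
            raise PackingError(
                f"cannot place segment of length >= {lo} in protein of length {n}"
            )
    return segs


def generate_tracks(
    record: ProteinRecord,
    config: GeneratorConfig,
    seed: int = 0,
) -> ProteinRecord:
    """Materialise a record's segment counts as per-residue tracks.

    Segments of each kind are placed uniformly without overlap (a configurable
    rate lets a segment ignore other kinds' occupancy, producing the small
    residue-level cross-overlap real predictor output shows).  The two
    disorder predictor tracks each keep a consensus residue with probability
    ``disorder_agreement``; at 1.0 the stringent consensus pipeline recovers
    the placed IDR segments exactly.
    """
    rng = np.random.default_rng(seed)
    n = record.length
    occupied = np.zeros(n, dtype=bool)
    tracks: dict[str, ResidueTrack] = {}

    for kind in ("DOM", "TMH", "CC10", "IDR10", "LCR"):
        count = int(record.counts.get(kind, 0))
        own = np.zeros(n, dtype=bool)
        segs = _place_segments(
            occupied, count, SEGMENT_LENGTH_RANGES[kind], rng,
            ignore_occupancy_p=config.cross_overlap_rate, own=own,
        )
        if kind == "IDR10":
            a = config.disorder_agreement
            consensus = np.zeros(n, dtype=np.uint8)
            for s, e in segs:
                consensus[s - 1 : e] = 1
            for name in ("idr_iupred", "idr_vsl2b"):
                bits = consensus.copy()
                if a < 1.0:
                    keep = rng.random(n) < a
                    bits = bits * keep
                tracks[name] = ResidueTrack.from_bits(name, bits)
        else:
            for name in _KIND_TO_TRACKS[kind]:
                tracks[name] = ResidueTrack(name, n, list(segs))
    for name in ("sah", "collagen"):
        tracks[name] = ResidueTrack(name, n, [])
    record.tracks.update(tracks)
    return record


def generate_records(
    table: pd.DataFrame,
    config: GeneratorConfig,
    seed: int = 0,
    with_tracks: bool = True,
) -> list[ProteinRecord]:
    """Build ProteinRecord objects (counts and, optionally, tracks) from a
    generated feature table."""
    rng = np.random.default_rng(seed)
    count_name_map = {
        "Ph": "phospho", "Ub": "ubiq", "methyl": "methyl", "acetyl": "acetyl",
        "ELM": "elm_ligdoc", "isoforms": "isoforms", "ppi_degree": "ppi_degree",
    }
    records = []
    for pid, row in table.iterrows():
        counts = {tgt: int(row[src]) for src, tgt in count_name_map.items()}
        counts.update({k: int(row[k]) for k in ("DOM", "CC10", "IDR10", "TMH", "LCR")})
        rec = ProteinRecord(id=str(pid), length=int(row["length"]), counts=counts)
        if with_tracks:
            rec = generate_tracks(rec, config, seed=int(rng.integers(2**31 - 1)))
        records.append(rec)
    return records


# ---------------------------------------------------------------------------
# Sequence generation
# ---------------------------------------------------------------------------

def generate_sequences(
    records: list[ProteinRecord],
    config: GeneratorConfig,
    seed: int = 0,
    strata: dict[str, str] | None = None,
) -> list[ProteinRecord]:
    """Draw residue strings from set-specific composition.

    ``strata`` maps protein id to stratum (default: proteome-like for all).
    Compositions are i.i.d. draws — realistic local sequence structure is out
    of scope; composition statistics are what downstream features consume.
    """
    rng = np.random.default_rng(seed)
    letters = np.array(list(STANDARD_RESIDUES))
    for rec in records:
        stratum = (strata or {}).get(rec.id, "proteome_only")
        p = _stratum_composition(stratum, config.effect_scale)
        seq = "".join(letters[rng.choice(20, size=rec.length, p=p)])
        rec.sequence = seq
    return records


def plant_homolog_family(
    records: list[ProteinRecord],
    member_ids: list[str],
    identity: float = 0.95,
    seed: int = 0,
) -> list[ProteinRecord]:
    """Overwrite the sequences of ``member_ids`` with mutated copies of the
    first member's sequence at the stated pairwise identity (same lengths)."""
    rng = np.random.default_rng(seed)
    by_id = {r.id: r for r in records}
    template = by_id[member_ids[0]]
    if template.sequence is None:
        raise ValueError("template has no sequence")
    letters = np.array(list(STANDARD_RESIDUES))
    base = np.array(list(template.sequence))
    for pid in member_ids[1:]:
        rec = by_id[pid]
        seq = base.copy()
        n = min(len(seq), rec.length)
        mutate = rng.random(n) > identity
        repl = letters[rng.integers(0, 20, size=int(mutate.sum()))]
        seq[:n][mutate] = repl
        if rec.length <= len(seq):
            rec.sequence = "".join(seq[: rec.length])
        else:
            tail = letters[rng.integers(0, 20, size=rec.length - len(seq))]
            rec.sequence = "".join(seq) + "".join(tail)
    return records
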