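"""Diversity of Potential Interactions (DPI) and set-comparison statistics.

The DPI score summarises how many distinct kinds of interaction-capable
elements a protein carries:

    DPI = ln(DOM) + ln(CC10) + ln(IDR10) + ln(TMH) + ln(Ph + Ub) + ln(ELM)

with DOM the domain count, CC10/IDR10 the numbers of coiled coils and
disordered regions longer than ten residues, TMH the transmembrane-helix
count, Ph/Ub phosphorylation and ubiquitination site counts and ELM the
number of LIG/DOC linear motifs.  The raw sum is undefined whenever any term
is zero, so the default convention replaces each ln(x) by ln(1 + x): DPI is 0
for a featureless protein, monotone in every argument, and the ranking of
proteins with positive counts is essentially preserved.  The raw ln(x) variant
(zero terms dropped) is available via ``zero_convention="drop"``.

Set comparisons use bootstrap enrichment (log-ratio of resampled feature
means, replicate count 1000, sample size 80% of the smallest set), a
non-overlap interval rule mapping 1/2/3-SD separation to p < 0.32 / 0.05 /
0.01, two-sample Kolmogorov–Smirnov tests, Yates-corrected chi-square on
above/below-mean contingency tables, and Spearman rank correlations.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

#: Column names of the six DPI term groups in a feature table.
DPI_TERMS = ("DOM", "CC10", "IDR10", "TMH", "Ph_Ub", "ELM")


@dataclass
class EnrichmentResult:
    feature: str
    log_ratio_mean: float
    log_ratio_sd: float
    p_level: str  # "ns", "0.32", "0.05" or "0.01"
    undefined_replicates: int = 0

    @property
    def undefined(self) -> bool:
        return self.undefined_replicates > 0


@dataclass
class TestResult:
    statistic: float
    p_value: float
    test: str


# ---------------------------------------------------------------------------
# DPI
# ---------------------------------------------------------------------------

def dpi_terms(fv) -> np.ndarray:
    """Extract the six DPI term counts (Ph and Ub pooled) from a mapping,
    Series or DataFrame row with DOM/CC10/IDR10/TMH/Ph/Ub/ELM entries."""
    get = fv.get if hasattr(fv, "get") else fv.__getitem__
    vals = np.array(
        [
            get("DOM"),
            get("CC10"),
            get("IDR10"),
            get("TMH"),
            get("Ph") + get("Ub"),
            get("ELM"),
        ],
        dtype=float,
    )
    return vals


def dpi(fv, zero_convention: str = "log1p") -> float:
    """DPI of one feature vector.

    ``zero_convention="log1p"`` (default) evaluates sum of ln(1 + x);
    ``"drop"`` evaluates sum of ln(x) over strictly positive terms only.
    """
    vals = dpi_terms(fv)
    if (vals < 0).any():
        raise ValueError("negative count in DPI terms")
    if zero_convention == "log1p":
        return float(np.log1p(vals).sum())
    if zero_convention == "drop":
        pos = vals[vals > 0]
        return float(np.log(pos).sum()) if pos.size else 0.0
    raise ValueError(f"unknown zero convention {zero_convention!r}")


def dpi_column(table: pd.DataFrame, zero_convention: str = "log1p") -> pd.Series:
    """Vectorized DPI over a feature table with DOM/CC10/IDR10/TMH/Ph/Ub/ELM."""
    terms = np.column_stack(
        [
            table["DOM"],
            table["CC10"],
            table["IDR10"],
            table["TMH"],
            table["Ph"] + table["Ub"],
            table["ELM"],
        ]
    ).astype(float)
    if (terms < 0).any():
        raise ValueError("negative count in DPI terms")
    if zero_convention == "log1p":
        out = np.log1p(terms).sum(axis=1)
    elif zero_convention == "drop":
        with np.errstate(divide="ignore"):
            logs = np.where(terms > 0, np.log(np.maximum(terms, 1e-300)), 0.0)
        out = logs.sum(axis=1)
    else:
        raise ValueError(f"unknown zero convention {zero_convention!r}")
    return pd.Series(out, index=table.index, name="dpi")


# ---------------------------------------------------------------------------
# Spearman correlation
# ---------------------------------------------------------------------------

EXACT_PERMUTATION_MAX_N = 8  # n! enumeration is feasible only for tiny n


def spearman_corr(x, y) -> TestResult:
    """Spearman rank correlation with average ranks for ties.

    The p-value is by exhaustive permutation enumeration for n <= 8 (two-sided,
    on |rho|) and by the t-approximation for larger n.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need two equal-length vectors with n >= 3")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        raise ValueError("undefined correlation: zero variance in ranks")
    rho = float(np.corrcoef(rx, ry)[0, 1])
    n = x.size
    if n <= EXACT_PERMUTATION_MAX_N:
        hits = 0
        total = 0
        for perm in itertools.permutations(range(n)):
            r = np.corrcoef(rx, ry[list(perm)])[0, 1]
            hits += abs(r) >= abs(rho) - 1e-12
            total += 1
        p = hits / total
    else:
        t = rho * math.sqrt((n - 2) / max(1e-300, 1 - rho**2))
        p = float(2 * stats.t.sf(abs(t), df=n - 2))
    return TestResult(statistic=rho, p_value=min(p, 1.0), test="spearman")


# ---------------------------------------------------------------------------
# Interval significance rule
# ---------------------------------------------------------------------------

P_LEVELS = {1: "0.32", 2: "0.05", 3: "0.01"}


def interval_significance(
    mean_a: float, sd_a: float, mean_b: float, sd_b: float
) -> str:
    """Significance level from non-overlap of mean ± k·SD intervals.

    The largest k in {1, 2, 3} for which the two intervals are disjoint maps
    to p < 0.32 / 0.05 / 0.01; overlap already at k = 1 is ``"ns"``.
    """
    if sd_a < 0 or sd_b < 0:
        raise ValueError("negative standard deviation")
    level = "ns"
    for k in (1, 2, 3):
        lo_a, hi_a = mean_a - k * sd_a, mean_a + k * sd_a
        lo_b, hi_b = mean_b - k * sd_b, mean_b + k * sd_b
        if hi_a < lo_b or hi_b < lo_a:
            level = P_LEVELS[k]
        else:
            break
    return level


# ---------------------------------------------------------------------------
# Bootstrap enrichment
# ---------------------------------------------------------------------------

def bootstrap_sample_size(smallest_set_size: int, fraction: float = 0.8,
                          rule: str = "half_up") -> int:
    """Resample size derived from the smallest set (80% of it by default).

    ``half_up`` rounds 0.8 x 51 = 40.8 to 41; ``floor`` is also available.
    """
    raw = fraction * smallest_set_size
    if rule == "half_up":
        return int(math.floor(raw + 0.5))
    if rule == "floor":
        return int(math.floor(raw))
    raise ValueError(f"unknown rounding rule {rule!r}")


def bootstrap_enrichment(
    subset: pd.DataFrame,
    reference: pd.DataFrame,
    n_rep: int = 1000,
    sample_size: int | None = None,
    seed: int = 0,
    with_replacement: bool = True,
) -> list[EnrichmentResult]:
    """Bootstrap log-enrichment of feature means, subset vs reference.

    Per replicate, ``sample_size`` proteins are drawn (with replacement by
    default) from each table and per-feature means taken; the statistic is
    ln(mean_subset / mean_reference).  Reported per feature: mean and SD of
    the replicate log-ratios, and a significance level from the interval rule
    applied to the two sampled-mean distributions.  Replicates where the
    reference mean is zero leave the feature flagged via
    ``undefined_replicates`` rather than silently dropped.
    """
    features = [c for c in subset.columns if c in reference.columns]
    if sample_size is None:
        sample_size = bootstrap_sample_size(min(len(subset), len(reference)))
    if sample_size > min(len(subset), len(reference)) and not with_replacement:
        raise ValueError("sample_size exceeds a table for drawing without replacement")
    rng = np.random.default_rng(seed)
    sub = subset[features].to_numpy(dtype=float)
    ref = reference[features].to_numpy(dtype=float)

    def draw_means(tab: np.ndarray) -> np.ndarray:
        n = tab.shape[0]
        if with_replacement:
            idx = rng.integers(0, n, size=(n_rep, sample_size))
        else:
            idx = np.stack(
                [rng.permutation(n)[:sample_size] for _ in range(n_rep)]
            )
        return tab[idx].mean(axis=1)  # (n_rep, n_features)

    m_sub = draw_means(sub)
    m_ref = draw_means(ref)
    results = []
    for j, feat in enumerate(features):
        bad = int((m_ref[:, j] == 0).sum()) + int((m_sub[:, j] == 0).sum())
        ok = (m_ref[:, j] > 0) & (m_sub[:, j] > 0)
        if ok.sum() == 0:
            results.append(EnrichmentResult(feat, math.nan, math.nan, "ns", bad))
            continue
        log_ratio = np.log(m_sub[ok, j] / m_ref[ok, j])
        level = interval_significance(
            float(m_sub[:, j].mean()),
            float(m_sub[:, j].std(ddof=1)),
            float(m_ref[:, j].mean()),
            float(m_ref[:, j].std(ddof=1)),
        )
        results.append(
            EnrichmentResult(
                feature=feat,
                log_ratio_mean=float(log_ratio.mean()),
                log_ratio_sd=float(log_ratio.std(ddof=1)) if log_ratio.size > 1 else 0.0,
                p_level=level,
                undefined_replicates=bad,
            )
        )
    return results


# ---------------------------------------------------------------------------
# KS and chi-square tests
# ---------------------------------------------------------------------------

def ks_feature_test(subset_values, proteome_values) -> TestResult:
    """Two-sample two-sided Kolmogorov–Smirnov test (asymptotic p)."""
    a = np.asarray(subset_values, dtype=float)
    b = np.asarray(proteome_values, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty sample")
    res = stats.ks_2samp(a, b, alternative="two-sided", method="asymp")
    return TestResult(statistic=float(res.statistic), p_value=float(res.pvalue), test="KS")


def yates_chi2(table: np.ndarray) -> TestResult:
    """Yates-continuity-corrected chi-square on a 2x2 table (1 df)."""
    table = np.asarray(table, dtype=float)
    if table.shape != (2, 2):
        raise ValueError("need a 2x2 table")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("degenerate table: zero marginal")
    stat, p, _, _ = stats.chi2_contingency(table, correction=True)
    return TestResult(statistic=float(stat), p_value=float(p), test="chi2_yates")


def chi2_above_below(
    subset: pd.DataFrame,
    complement: pd.DataFrame,
    feature: str,
    threshold: float,
) -> TestResult:
    """Yates chi-square on the 2x2 above/below-threshold contingency table.

    ``threshold`` is conventionally the proteome mean of the feature; rows are
    subset vs complement, columns are value > threshold vs value <= threshold.
    """
    if len(subset) == 0 or len(complement) == 0:
        raise ValueError("empty table")
    a = np.asarray(subset[feature], dtype=float)
    b = np.asarray(complement[feature], dtype=float)
    table = np.array(
        [
            [(a > threshold).sum(), (a <= threshold).sum()],
            [(b > threshold).sum(), (b <= threshold).sum()],
        ],
        dtype=float,
    )
    return yates_chi2(table)


# ---------------------------------------------------------------------------
# Set-level DPI vs PPI correlation
# ---------------------------------------------------------------------------

def set_dpi_ppi_correlation(set_tables: list[pd.DataFrame]) -> TestResult:
    """Spearman correlation between per-set mean DPI and mean PPI degree.

    Each table needs a ``dpi`` column (add one with :func:`dpi_column`) and a
    ``ppi_degree`` column; the correlation is over per-set arithmetic means.
    """
    if len(set_tables) < 3:
        raise ValueError("need at least 3 sets")
    mean_dpi = [float(t["dpi"].mean()) for t in set_tables]
    mean_ppi = [float(t["ppi_degree"].mean()) for t in set_tables]
    return spearman_corr(mean_dpi, mean_ppi)


def enrichment_to_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    """Tidy per-feature enrichment table for TSV export."""
    return pd.DataFrame(
        {
            "feature": [r.feature for r in results],
            "log_ratio_mean": [r.log_ratio_mean for r in results],
            "log_ratio_sd": [r.log_ratio_sd for r in results],
            "p_level": [r.p_level for r in results],
            "undefined_replicates": [r.undefined_replicates for r in results],
        }
    )
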