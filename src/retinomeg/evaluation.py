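"""Localization-accuracy framework: thresholding, accuracy, group statistics.

A reconstruction is reduced to an *active set* — the top q percent of
vertices by statistic value across the whole source space.  Localization
accuracy for a stimulus is the percentage of active vertices inside an ROI
(a visual area, or the eccentricity-band complex) that fall in the
retinotopically expected subregion; chance is 25% for the four angular
subregions of V1-V3, 50% for V3A (left/right only) and 33.3% for the
three eccentricity bands.  The threshold q is swept over a grid and fixed,
per subject and method, at the value maximizing mean accuracy across that
subject's stimuli (zero-active reconstructions count as zero during the
sweep).  Group-level inference uses exact Wilcoxon signed-rank tests
against chance, Kruskal-Wallis comparisons between methods, and Bonferroni
correction over each stimulus set's comparison family.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil

import numpy as np
import pandas as pd
from scipy import stats

from .atlas import RetinotopicAtlas, expected_subregion
from .minimum_norm import SourceEstimate

DEFAULT_Q_GRID = (0.1, 0.2, 0.5, 1.0, 2.0, 5.0, 10.0)

#: Bonferroni family sizes per stimulus set (tests across areas x methods)
BONFERRONI_FAMILY = {"quadrants": 16, "rings": 9, "quarter_rings": 4}


@dataclass(frozen=True)
class ActiveSet:
    indices: np.ndarray
    q_percent: float
    cutoff: float
    n_vertices: int

    @property
    def mask(self) -> np.ndarray:
        m = np.zeros(self.n_vertices, dtype=bool)
        m[self.indices] = True
        return m


@dataclass(frozen=True)
class AccuracyRecord:
    stimulus: str
    selector: object
    percent: float          # nan when excluded
    chance: float
    n_active_in_roi: int
    excluded: bool
    method: str = ""
    subject: str = ""


@dataclass(frozen=True)
class GroupStats:
    test: str
    statistic: float
    n: int
    p: float
    degenerate: bool = False


def threshold_active(est: SourceEstimate | np.ndarray, q: float) -> ActiveSet:
    """Vertices whose statistic reaches the (100-q)th percentile cutoff.

    The cutoff is the q-th largest value; ties at the cutoff are all
    included, so the active set never falls below ceil(q% of n).
    """
    values = est.values if isinstance(est, SourceEstimate) else np.asarray(est)
    n = len(values)
    if n == 0:
        raise ValueError("empty source estimate")
    if not np.all(np.isfinite(values)):
        raise ValueError("non-finite statistic values")
    if not 0 < q <= 100:
        raise ValueError("q must be in (0, 100]")
    k = ceil(q / 100.0 * n)
    cutoff = np.sort(values)[n - k]
    return ActiveSet(
        indices=np.flatnonzero(values >= cutoff), q_percent=q,
        cutoff=float(cutoff), n_vertices=n,
    )


def localization_accuracy(
    active: ActiveSet,
    atlas: RetinotopicAtlas,
    stimulus,
    selector,
    method: str = "",
    subject: str = "",
) -> AccuracyRecord:
    """Percent of active-in-ROI vertices inside the expected subregion.

    Reconstructions with no active vertex in the ROI are flagged excluded
    (percent = nan), mirroring the exclusion rule for failed localizations.
    """
    region = expected_subregion(stimulus, atlas, selector)
    m = active.mask
    n_roi = int((m & region.roi).sum())
    if n_roi == 0:
        return AccuracyRecord(stimulus.name, selector, np.nan, region.chance,
                              0, True, method, subject)
    n_hit = int((m & region.expected).sum())
    return AccuracyRecord(stimulus.name, selector, 100.0 * n_hit / n_roi,
                          region.chance, n_roi, False, method, subject)


def optimize_threshold(
    estimates: dict,
    atlas: RetinotopicAtlas,
    selector,
    q_grid=DEFAULT_Q_GRID,
) -> tuple[float, pd.DataFrame]:
    """Sweep q over the grid; return (optimal q, accuracy curve).

    ``estimates`` maps StimulusSpec -> SourceEstimate for one subject and
    method.  For each q the objective is the mean accuracy across stimuli
    with zero-active reconstructions scored as zero; the optimal q is the
    argmax, ties resolved toward the smallest q.
    """
    grid = sorted(q_grid)
    if not grid:
        raise ValueError("empty q grid")
    rows = []
    for q in grid:
        accs = []
        for stim, est in estimates.items():
            rec = localization_accuracy(threshold_active(est, q), atlas,
                                        stim, selector)
            accs.append(0.0 if rec.excluded else rec.percent)
        rows.append({"q": q, "mean_accuracy": float(np.mean(accs))})
    curve = pd.DataFrame(rows)
    q_opt = float(curve.loc[curve["mean_accuracy"].idxmax(), "q"])
    return q_opt, curve


# ---------------------------------------------------------------------------
# nonparametric group statistics


def _signed_rank_exact_p(ranks2: np.ndarray, w2_obs: float) -> float:
    """P(W+ >= w_obs) under random signs, by generating-function enumeration.

    ``ranks2`` are the (tie-averaged) ranks doubled to integers; ``w2_obs``
    the doubled observed statistic.
    """
    total = int(ranks2.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in ranks2.astype(int):
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    counts /= counts.sum()
    lo = int(np.ceil(w2_obs - 1e-9))
    return float(counts[lo:].sum())


def signrank_vs_chance(
    accuracies,
    chance: float,
    alternative: str = "greater",
    exact_max_n: int = 25,
) -> GroupStats:
    """Wilcoxon signed-rank test of accuracies against the chance level.

    Exact null by enumeration for n <= 25 (after dropping zero
    differences); normal approximation with continuity and tie correction
    above.  One-sided "greater" is the default, matching the hypothesis
    that sources localize to the expected subregion better than chance.
    """
    a = np.asarray(list(accuracies), dtype=float)
    a = a[~np.isnan(a)]
    d = a - chance
    d = d[d != 0.0]
    n = len(d)
    if n == 0:
        return GroupStats("wilcoxon_signrank", np.nan, 0, np.nan, degenerate=True)
    if n < 5:
        raise ValueError("need at least 5 nonzero differences")
    ranks = stats.rankdata(np.abs(d))
    w_plus = ranks[d > 0].sum()
    if n <= exact_max_n:
        ranks2 = np.round(2 * ranks)
        p_hi = _signed_rank_exact_p(ranks2, 2 * w_plus)
        p_lo = _signed_rank_lower_p(ranks2, 2 * w_plus)
        if alternative == "greater":
            p = p_hi
        elif alternative == "less":
            p = p_lo
        else:
            p = min(1.0, 2.0 * min(p_hi, p_lo))
    else:
        mean = n * (n + 1) / 4.0
        _, tie_counts = np.unique(ranks, return_counts=True)
        var = n * (n + 1) * (2 * n + 1) / 24.0 - (
            (tie_counts**3 - tie_counts).sum() / 48.0
        )
        if alternative == "greater":
            z = (w_plus - mean - 0.5) / np.sqrt(var)
            p = float(stats.norm.sf(z))
        elif alternative == "less":
            z = (w_plus - mean + 0.5) / np.sqrt(var)
            p = float(stats.norm.cdf(z))
        else:
            z = (abs(w_plus - mean) - 0.5) / np.sqrt(var)
            p = float(2 * stats.norm.sf(z))
    return GroupStats("wilcoxon_signrank", float(w_plus), n, min(1.0, p))


def _signed_rank_lower_p(ranks2: np.ndarray, w2_obs: float) -> float:
    """P(W+ <= w_obs), exact."""
    return 1.0 - _signed_rank_exact_p(ranks2, w2_obs + 1.0)


def kruskal_wallis(groups) -> GroupStats:
    """Rank-based Kruskal-Wallis H with tie correction, chi^2 reference."""
    groups = [np.asarray(list(g), dtype=float) for g in groups]
    groups = [g[~np.isnan(g)] for g in groups]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 values each")
    pooled = np.concatenate(groups)
    n_total = len(pooled)
    if np.all(pooled == pooled[0]):
        return GroupStats("kruskal_wallis", 0.0, n_total, np.nan, degenerate=True)
    ranks = stats.rankdata(pooled)
    h = 0.0
    start = 0
    for g in groups:
        r = ranks[start:start + len(g)]
        start += len(g)
        h += len(g) * (r.mean() - (n_total + 1) / 2.0) ** 2
    h *= 12.0 / (n_total * (n_total + 1))
    _, tie_counts = np.unique(pooled, return_counts=True)
    correction = 1.0 - (tie_counts**3 - tie_counts).sum() / (n_total**3 - n_total)
    h /= correction
    df = len(groups) - 1
    return GroupStats("kruskal_wallis", float(h), n_total,
                      float(stats.chi2.sf(h, df)))


def bonferroni(raw_p, family_size: int, alpha: float = 0.05):
    """Corrected significance: raw p < alpha / m.

    Returns (significant, corrected_alpha, corrected_p) with corrected p
    values capped at 1.  Accepts a scalar or a sequence.
    """
    if family_size < 1:
        raise ValueError("family size must be >= 1")
    p = np.asarray(raw_p, dtype=float)
    corrected_alpha = alpha / family_size
    significant = p < corrected_alpha
    corrected_p = np.minimum(1.0, p * family_size)
    if p.ndim == 0:
        return bool(significant), corrected_alpha, float(corrected_p)
    return significant, corrected_alpha, corrected_p
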