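"""Statistical validation for the split-mouth grading study.

The cleft side of each patient is compared with the contralateral
(noncleft) control side, so all tests are paired: an exact Wilcoxon
signed-rank test (sign-flip distribution computed over all 2^m
assignments of the m nonzero differences), unweighted Cohen's kappa for
intra-/inter-rater agreement over the rated sites, and a bootstrap
estimate of the test's power with the critical value calibrated under
the null that both sides follow the control distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import ASSESSMENT_LEVELS_MM


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    n_effective: int
    method_detail: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value must lie in [0, 1]")


@dataclass(frozen=True)
class PowerResult:
    power: float
    p_critical: float
    alpha: float
    n_reps: int
    seed: int
    method_detail: str

    def __float__(self) -> float:
        return self.power


def _signed_rank_statistic(
    d: np.ndarray, zero_method: str
) -> tuple[float, np.ndarray, int]:
    """W+ statistic, the midranks entering it, and the effective n."""
    d = np.asarray(d, float)
    if zero_method == "discard":
        d = d[d != 0]
        ranks = sps.rankdata(np.abs(d)) if d.size else np.array([])
        w_plus = float(ranks[d > 0].sum()) if d.size else 0.0
        return w_plus, ranks, int(d.size)
    if zero_method == "pratt":
        ranks_all = sps.rankdata(np.abs(d))
        nz = d != 0
        ranks = ranks_all[nz]
        w_plus = float(ranks_all[d > 0].sum())
        return w_plus, ranks, int(nz.sum())
    raise ValueError("zero_method must be 'discard' or 'pratt'")


def _exact_two_sided_p(w_plus: float, ranks: np.ndarray) -> float:
    """Exact two-sided p via the sign-flip distribution of W+.

    Midranks are doubled to integers; the distribution over all 2^m sign
    assignments is built by polynomial convolution (equivalent to full
    enumeration).  p = min(1, 2 * min(P(W+ <= w), P(W+ >= w))).
    """
    r2 = np.rint(2 * np.asarray(ranks, float)).astype(np.int64)
    total = int(r2.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: counts.size - r]
        counts = counts + shifted
    denom = 2.0 ** len(r2)
    w2 = int(np.rint(2 * w_plus))
    p_le = counts[: w2 + 1].sum() / denom
    p_ge = counts[w2:].sum() / denom
    return min(1.0, 2.0 * min(p_le, p_ge))


def _normal_approx_p(w_plus: float, ranks: np.ndarray) -> float:
    m = len(ranks)
    mu = m * (m + 1) / 4.0
    var = m * (m + 1) * (2 * m + 1) / 24.0
    # midrank tie correction
    _, tie_counts = np.unique(ranks, return_counts=True)
    var -= (tie_counts**3 - tie_counts).sum() / 48.0
    if var <= 0:
        return 1.0
    # continuity correction toward the mean (statistic lives on a half-integer grid)
    shift = w_plus - mu
    shift -= 0.5 * np.sign(shift)
    z = shift / np.sqrt(var)
    return float(min(1.0, 2 * sps.norm.sf(abs(z))))


def wilcoxon_signed_rank(
    x,
    y,
    zero_method: str = "discard",
    mode: str = "auto",
    exact_threshold: int = 25,
) -> TestResult:
    """Paired Wilcoxon signed-rank test on differences ``x - y``.

    ``zero_method='discard'`` drops zero differences before ranking (the
    classic reduction); ``'pratt'`` ranks zeros but excludes them from the
    statistic.  ``mode='exact'`` always uses the sign-flip distribution;
    ``'auto'`` switches to a tie-corrected normal approximation for more
    than ``exact_threshold`` nonzero differences.  If every difference is
    zero the test reports p = 1 by convention.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1D arrays")
    if x.size < 1:
        raise ValueError("need at least one pair")
    d = x - y
    w_plus, ranks, m = _signed_rank_statistic(d, zero_method)
    if m == 0:
        return TestResult(
            statistic=0.0, p_value=1.0, n_effective=0,
            method_detail=f"all differences zero (zero_method={zero_method}); "
            "p=1 by convention",
        )
    use_exact = mode == "exact" or (mode == "auto" and m <= exact_threshold)
    if use_exact:
        p = _exact_two_sided_p(w_plus, ranks)
        detail = (
            f"exact sign-flip distribution over 2^{m} assignments; midranks for "
            f"ties; zero_method={zero_method}; two-sided p=2*min(P<=,P>=) capped at 1"
        )
    else:
        p = _normal_approx_p(w_plus, ranks)
        detail = (
            f"normal approximation with tie correction (m={m} > "
            f"{exact_threshold}); zero_method={zero_method}; two-sided"
        )
    return TestResult(statistic=w_plus, p_value=p, n_effective=m, method_detail=detail)


def cohen_kappa(ratings_a, ratings_b, categories=(0, 1, 2, 3)) -> float:
    """Unweighted Cohen's kappa between two rating series of the same sites.

    kappa = (p_o - p_e) / (1 - p_e) with observed agreement p_o and chance
    agreement p_e from the raters' marginals.  Full agreement concentrated
    on a single category (p_o = p_e = 1) returns 1 by convention.
    """
    a = np.asarray(ratings_a)
    b = np.asarray(ratings_b)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("rating vectors must be equal-length and 1D")
    if a.size == 0:
        raise ValueError("need at least one rated site")
    cats = np.asarray(categories)
    if not (np.isin(a, cats).all() and np.isin(b, cats).all()):
        raise ValueError(f"ratings must come from categories {list(categories)}")
    n = a.size
    table = np.zeros((cats.size, cats.size))
    ai = np.searchsorted(cats, a)
    bi = np.searchsorted(cats, b)
    np.add.at(table, (ai, bi), 1.0)
    p_o = np.trace(table) / n
    p_e = float((table.sum(axis=1) / n) @ (table.sum(axis=0) / n))
    if p_e >= 1.0 - 1e-15:
        return 1.0 if p_o >= 1.0 - 1e-15 else 0.0
    return float((p_o - p_e) / (1.0 - p_e))


def bootstrap_power(
    cleft,
    control,
    alpha: float = 0.05,
    n_reps: int = 10_000,
    seed: int = 0,
    zero_method: str = "discard",
) -> PowerResult:
    """Bootstrap power of the paired signed-rank test.

    H0: both sides are drawn from the control (noncleft) empirical
    distribution; H1: the sides differ as observed, i.e. the cleft side is
    drawn from the cleft empirical distribution.  The critical p-value is
    calibrated on ``n_reps`` H0 replicates (the floor(alpha*n_reps)-th
    smallest p), then power is the rejection fraction over ``n_reps`` H1
    replicates.  Sides are resampled independently: the patient-level
    pairing is not part of the stated hypotheses.
    """
    cleft = np.asarray(cleft, float)
    control = np.asarray(control, float)
    if cleft.size == 0 or control.size == 0:
        raise ValueError("both score vectors must be nonempty")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if n_reps < 1:
        raise ValueError("n_reps must be positive")
    detail = (
        "independent resampling of sides from their empirical distributions; "
        f"critical value calibrated on {n_reps} H0 replicates (both sides from "
        f"control); zero_method={zero_method}; seed={seed}"
    )
    if (
        np.unique(cleft).size == 1
        and np.unique(control).size == 1
        and cleft[0] == control[0]
    ):
        return PowerResult(
            power=float(alpha), p_critical=float("nan"), alpha=alpha,
            n_reps=n_reps, seed=seed,
            method_detail=detail + "; degenerate identical one-point "
            "distributions: power = alpha by convention",
        )
    rng = np.random.default_rng(seed)
    n = cleft.size

    def _pvals(x_pool: np.ndarray, y_pool: np.ndarray) -> np.ndarray:
        ps = np.empty(n_reps)
        for i in range(n_reps):
            x = rng.choice(x_pool, size=n, replace=True)
            y = rng.choice(y_pool, size=n, replace=True)
            ps[i] = wilcoxon_signed_rank(x, y, zero_method=zero_method).p_value
        return ps

    p_null = np.sort(_pvals(control, control))
    k = max(int(np.floor(alpha * n_reps)), 1)
    p_crit = float(p_null[k - 1])
    p_alt = _pvals(cleft, control)
    power = float(np.mean(p_alt <= p_crit))
    return PowerResult(
        power=power, p_critical=p_crit, alpha=alpha, n_reps=n_reps,
        seed=seed, method_detail=detail,
    )


def summarize_sites(scores: pd.DataFrame, side: str) -> dict:
    """Per-level 0-3 score counts for one side, plus pooled totals.

    ``scores`` is a long-format table with columns patient_id, side,
    level_mm, score (one row per site per patient).
    """
    sub = scores[scores["side"] == side]
    missing = [
        int(lv) for lv in ASSESSMENT_LEVELS_MM
        if int(lv) not in set(sub["level_mm"].astype(int))
    ]
    if sub.empty or missing:
        raise ValueError(
            f"score table incomplete for side '{side}': missing levels {missing or 'all'}"
        )
    levels = [int(lv) for lv in ASSESSMENT_LEVELS_MM]
    table = pd.DataFrame(0, index=levels, columns=[0, 1, 2, 3])
    counted = (
        sub.groupby([sub["level_mm"].astype(int), sub["score"].astype(int)])
        .size()
        .unstack(fill_value=0)
    )
    table.update(counted)
    table = table.astype(int)
    table.index.name = "level_mm"
    table.columns.name = "score"
    pooled = table.sum(axis=0)
    return {
        "per_level": table,
        "pooled": pooled,
        "n_sites": int(table.values.sum()),
    }


def _round_half_up(value: float, decimals: int = 2) -> float:
    from decimal import ROUND_HALF_UP, Decimal

    q = Decimal(10) ** -decimals
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


def summarize_totals(totals_by_side: dict[str, np.ndarray]) -> dict:
    """Total-score counts, category percentages and medians per side.

    ``totals_by_side`` maps side name to one 0-12 total per patient.
    Percentages are printed half-up to two decimals; the median uses the
    midpoint convention for even n.
    """
    from .scoring import CATEGORY_BINS

    out: dict[str, dict] = {}
    for side, totals in totals_by_side.items():
        totals = np.asarray(totals, int)
        if totals.size == 0:
            raise ValueError(f"no totals for side '{side}'")
        if np.any((totals < 0) | (totals > 12)):
            raise ValueError("totals must lie in 0..12")
        counts = np.bincount(totals, minlength=13)
        n = totals.size
        pct = {
            cat: _round_half_up(100.0 * counts[lo : hi + 1].sum() / n)
            for cat, (lo, hi) in CATEGORY_BINS.items()
        }
        out[side] = {
            "counts": counts,
            "n": n,
            "category_pct": pct,
            "median": float(np.median(totals)),
        }
    return out


def expand_counts(counts) -> np.ndarray:
    """Expand a count vector over totals 0..12 into individual totals."""
    counts = np.asarray(counts, int)
    return np.repeat(np.arange(counts.size), counts)
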