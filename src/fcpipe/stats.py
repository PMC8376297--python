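"""Group comparisons and moderated brain-behavior regression.

Two-sample t tests (raw-data or summary-statistic form) cover the
behavioral and network-strength group comparisons.  The moderated
regression asks whether a binary group factor (e.g. a history of overt
hepatic encephalopathy) changes the slope between network strength and a
cognitive score:

    score ~ 1 + strength + moderator + strength x moderator

fit by OLS, with bias-corrected (BC) percentile bootstrap confidence
intervals for the unstandardized coefficients from nonparametric case
resampling (default 10,000 resamples, 95% level).  Predictors are
mean-centered before the interaction is formed, which changes only the
interpretation of the lower-order terms, never the interaction estimate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "ModerationResult",
    "two_sample_t",
    "summary_t",
    "moderated_regression",
]


def _finish_t(t: float, df: float, tails: str) -> tuple[float, float, float]:
    if tails == "two":
        p = 2.0 * stats.t.sf(abs(t), df)
    elif tails == "one":
        p = stats.t.sf(abs(t), df)
    else:
        raise ValueError("tails must be 'one' or 'two'")
    return float(t), float(df), float(min(p, 1.0))


def two_sample_t(
    a, b, tails: str = "two", variance: str = "pooled"
) -> tuple[float, float, float]:
    """Two-sample t test; returns ``(t, df, p)``.

    ``variance="pooled"`` is the classical Student test; ``"welch"`` drops
    the equal-variance assumption.  One-tailed p is reported in the
    direction of the observed difference.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 observations per group")
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        if a.mean() == b.mean():
            return 0.0, float(a.size + b.size - 2), 1.0
        raise ValueError("zero variance in both groups with unequal means")
    res = stats.ttest_ind(a, b, equal_var=(variance == "pooled"))
    return _finish_t(float(res.statistic), float(res.df), tails)


def summary_t(
    mean_a: float,
    sd_a: float,
    n_a: int,
    mean_b: float,
    sd_b: float,
    n_b: int,
    tails: str = "two",
    variance: str = "pooled",
) -> tuple[float, float, float]:
    """Two-sample t from printed summary statistics (mean, SD, n).

    Algebraically identical to :func:`two_sample_t` on raw data reduced
    to the same summaries; useful for checking published group tables.
    """
    if sd_a <= 0 or sd_b <= 0:
        raise ValueError("standard deviations must be positive")
    if n_a < 2 or n_b < 2:
        raise ValueError("need n >= 2 per group")
    res = stats.ttest_ind_from_stats(
        mean_a, sd_a, n_a, mean_b, sd_b, n_b, equal_var=(variance == "pooled")
    )
    if variance == "pooled":
        df = n_a + n_b - 2
    else:
        va, vb = sd_a**2 / n_a, sd_b**2 / n_b
        df = (va + vb) ** 2 / (va**2 / (n_a - 1) + vb**2 / (n_b - 1))
    return _finish_t(float(res.statistic), float(df), tails)


@dataclass
class ModerationResult:
    coef_names: list[str]
    coefficients: dict[str, float]
    ci: dict[str, tuple[float, float]]
    interaction_p: float
    n_boot: int
    ci_level: float
    seed: int | None
    n_redraws: int  # degenerate bootstrap resamples that were redrawn
    bootstrap_estimates: np.ndarray  # (n_boot, n_coef)

    @property
    def interaction(self) -> float:
        return self.coefficients["strength:moderator"]


def _design(
    strength: np.ndarray,
    moderator: np.ndarray,
    moderator2: np.ndarray | None,
    center: bool,
) -> tuple[np.ndarray, list[str]]:
    s = strength - strength.mean() if center else strength
    m = moderator - moderator.mean() if center else moderator
    cols = [np.ones_like(s), s, m, s * m]
    names = ["intercept", "strength", "moderator", "strength:moderator"]
    if moderator2 is not None:
        m2 = moderator2 - moderator2.mean() if center else moderator2
        cols += [m2, s * m2, m * m2, s * m * m2]
        names += [
            "moderator2",
            "strength:moderator2",
            "moderator:moderator2",
            "strength:moderator:moderator2",
        ]
    return np.column_stack(cols), names


def _bc_interval(
    boot: np.ndarray, estimate: float, ci_level: float
) -> tuple[float, float]:
    """Bias-corrected percentile interval (BC, no acceleration term)."""
    n = boot.size
    # midpoint convention for ties: z0 is exactly 0 when the bootstrap
    # median coincides with the estimate, so BC reduces to the percentile
    below = (boot < estimate).sum() + 0.5 * (boot == estimate).sum()
    prop = np.clip(below / n, 1.0 / (n + 1), n / (n + 1.0))
    z0 = stats.norm.ppf(prop)
    alpha = (1.0 - ci_level) / 2.0
    lo_q = stats.norm.cdf(2.0 * z0 + stats.norm.ppf(alpha))
    hi_q = stats.norm.cdf(2.0 * z0 + stats.norm.ppf(1.0 - alpha))
    return float(np.quantile(boot, lo_q)), float(np.quantile(boot, hi_q))


def moderated_regression(
    score,
    strength,
    moderator,
    n_boot: int = 10_000,
    ci_level: float = 0.95,
    seed: int | None = None,
    center: bool = True,
    moderator2=None,
) -> ModerationResult:
    """OLS moderation model with BC bootstrap confidence intervals.

    Parameters
    ----------
    score, strength
        Per-subject behavioral score and network strength.
    moderator
        Binary group indicator (both levels must appear at least 3 times).
    moderator2
        Optional second binary moderator; when given, the full three-way
        term set is fit and the reported ``interaction_p`` refers to the
        three-way ``strength:moderator:moderator2`` coefficient.
    n_boot, ci_level
        Nonparametric case-resampling bootstrap size and CI level.

    A bootstrap resample missing one moderator level leaves the
    interaction inestimable and is redrawn (the count is recorded).
    """
    y = np.asarray(score, dtype=float).ravel()
    s = np.asarray(strength, dtype=float).ravel()
    m = np.asarray(moderator, dtype=float).ravel()
    if not (y.size == s.size == m.size):
        raise ValueError("score, strength and moderator must have equal length")
    levels = np.unique(m)
    if levels.size != 2:
        raise ValueError("moderator must be binary with both levels present")
    if min((m == levels[0]).sum(), (m == levels[1]).sum()) < 3:
        raise ValueError("each moderator level needs at least 3 subjects")
    m2 = None
    if moderator2 is not None:
        m2 = np.asarray(moderator2, dtype=float).ravel()
        if np.unique(m2).size != 2:
            raise ValueError("moderator2 must be binary with both levels present")

    design, names = _design(s, m, m2, center)
    fit = sm.OLS(y, design).fit()
    estimates = np.asarray(fit.params, dtype=float)
    key = "strength:moderator:moderator2" if m2 is not None else "strength:moderator"
    interaction_p = float(fit.pvalues[names.index(key)])

    rng = np.random.default_rng(seed)
    n = y.size
    idx = rng.integers(0, n, size=(n_boot, n))
    n_redraws = 0
    # a valid resample must contain both levels of every binary moderator
    def _invalid(ix: np.ndarray) -> np.ndarray:
        bad = np.ptp(m[ix], axis=1) == 0.0
        if m2 is not None:
            bad |= np.ptp(m2[ix], axis=1) == 0.0
        return bad

    bad = _invalid(idx)
    while bad.any():
        n_redraws += int(bad.sum())
        idx[bad] = rng.integers(0, n, size=(int(bad.sum()), n))
        bad = _invalid(idx)
    if n_redraws:
        logger.info("redrew %d degenerate bootstrap resample(s)", n_redraws)

    # batched OLS over all resamples: solve (X'X) beta = X'y per resample
    xb = design[idx]  # (B, n, p)
    yb = y[idx]  # (B, n)
    gram = np.einsum("bni,bnj->bij", xb, xb)
    moment = np.einsum("bni,bn->bi", xb, yb)
    try:
        boot = np.linalg.solve(gram, moment[..., None])[..., 0]
    except np.linalg.LinAlgError:
        boot = np.empty_like(moment)
        for k in range(n_boot):
            boot[k], *_ = np.linalg.lstsq(xb[k], yb[k], rcond=None)

    ci = {
        name: _bc_interval(boot[:, j], estimates[j], ci_level)
        for j, name in enumerate(names)
    }
    return ModerationResult(
        coef_names=names,
        coefficients={name: float(estimates[j]) for j, name in enumerate(names)},
        ci=ci,
        interaction_p=interaction_p,
        n_boot=n_boot,
        ci_level=ci_level,
        seed=seed,
        n_redraws=n_redraws,
        bootstrap_estimates=boot,
    )
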