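"""Psychometric-function fitting and point-of-subjective-equality (PSE).

The proportion of sweep images classified LONG, as a function of the signed
top−bottom length difference, is fitted with a two-parameter logistic by
maximum likelihood on the binomial counts (a binomial GLM with logit link).
The PSE is the difference at which the fitted curve crosses 50%.

Sign convention: a *negative* PSE means the top line must be physically
shorter than the bottom one to be judged equal — i.e. the top (arrowtail)
line is illusorily elongated, the direction of the Müller-Lyer effect.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm


class FitError(ValueError):
    """Raised when a psychometric fit is degenerate or ill-posed."""


@dataclass
class PsychometricCurve:
    """Binomial counts of LONG responses per signed length difference."""

    diffs: np.ndarray        # signed top−bottom difference, pixels
    n_long: np.ndarray
    n_total: np.ndarray

    def __post_init__(self):
        self.diffs = np.asarray(self.diffs, dtype=np.float64)
        self.n_long = np.asarray(self.n_long, dtype=np.int64)
        self.n_total = np.asarray(self.n_total, dtype=np.int64)
        if not (len(self.diffs) == len(self.n_long) == len(self.n_total)):
            raise ValueError("curve arrays must have equal length")
        if np.any(self.n_long < 0) or np.any(self.n_long > self.n_total):
            raise ValueError("need 0 <= n_long <= n_total")

    @property
    def proportion_long(self) -> np.ndarray:
        return self.n_long / np.where(self.n_total > 0, self.n_total, 1)


@dataclass
class SigmoidFit:
    """A fitted logistic p(diff) = 1 / (1 + exp(-(a + b·diff)))."""

    intercept: float
    slope: float
    midpoint: float          # diff at p = 0.5, the PSE candidate
    deviance: float
    support: tuple           # (min diff, max diff) of the fitted data

    def predict(self, diffs) -> np.ndarray:
        z = self.intercept + self.slope * np.asarray(diffs, dtype=np.float64)
        return 1.0 / (1.0 + np.exp(-z))


def fit_sigmoid(curve: PsychometricCurve) -> SigmoidFit:
    """Maximum-likelihood logistic fit to the binomial counts.

    Degenerate data (fewer than 4 distinct differences, all responses LONG,
    or none) raise :class:`FitError` rather than extrapolating silently.
    """
    if len(np.unique(curve.diffs)) < 4:
        raise FitError("need at least 4 distinct length differences")
    total_long = int(curve.n_long.sum())
    if total_long == 0 or total_long == int(curve.n_total.sum()):
        raise FitError("degenerate curve: all responses on one side")
    endog = np.column_stack([curve.n_long, curve.n_total - curve.n_long])
    exog = sm.add_constant(curve.diffs)
    try:
        res = sm.GLM(endog, exog, family=sm.families.Binomial()).fit()
    except Exception as exc:       # perfect separation, singular designs, ...
        raise FitError(f"logistic fit failed: {exc}") from exc
    intercept, slope = (float(res.params[0]), float(res.params[1]))
    if slope == 0.0 or not np.isfinite(slope) or not np.isfinite(intercept):
        raise FitError("logistic fit did not converge to a finite slope")
    return SigmoidFit(intercept=intercept, slope=slope,
                      midpoint=-intercept / slope,
                      deviance=float(res.deviance),
                      support=(float(curve.diffs.min()), float(curve.diffs.max())))


def estimate_pse(fit: SigmoidFit) -> float:
    """The length difference at which the fitted curve crosses 50%.

    Raises :class:`FitError` when the crossing lies outside the range of
    differences the curve was fitted on (an extrapolated PSE is not
    trustworthy).
    """
    lo, hi = fit.support
    if not lo <= fit.midpoint <= hi:
        raise FitError(
            f"fitted 50% crossing {fit.midpoint:.1f} px lies outside the "
            f"measured range [{lo:.0f}, {hi:.0f}] px")
    return float(fit.midpoint)


def human_equivalent_pse(bias_fraction: float, len_min: float,
                         len_max: float) -> float:
    """Convert a fractional human illusion bias into pixels.

    A bias of, e.g., 26% applied to shafts drawn uniformly from
    [len_min, len_max] corresponds to a PSE of 0.26 × mean shaft length.
    """
    if not 0.0 <= bias_fraction <= 1.0:
        raise ValueError("bias_fraction must be in [0, 1]")
    if len_min > len_max:
        raise ValueError("len_min must not exceed len_max")
    return bias_fraction * (len_min + len_max) / 2.0
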