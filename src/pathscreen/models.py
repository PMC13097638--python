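"""Linearized least-squares fits of the four bivariate model forms and
relationship classification.

Each form is fitted by ordinary least squares on its linearizing
coordinates, matching spreadsheet trendline behaviour:

    linear        y = a*x + b          OLS on (x, y)
    logarithmic   y = a*ln(x) + b      OLS on (ln x, y)
    exponential   y = a*e^(b*x)        OLS on (x, ln y); a = exp(intercept)
    power         y = a*x^b            OLS on (ln x, ln y); a = exp(intercept)

The best form for a pair is the one with maximal |r| on its linearizing
coordinates; ties within a tolerance (default 0.01) are resolved toward
linear for parsimony.  The winning form carries a regulatory label from
the pathway taxonomy: linear = rheostat (graded, proportional control);
logarithmic, exponential and positive-exponent power = on-switch
(threshold-like activation); negative-exponent power = off-switch (mutual
exclusion).  The label is withheld (``none``) when even the best |r| is
below the strong-association threshold.

Whether the best nonlinear form improves on the linear one is tested with
the independent-samples Fisher r-to-z comparison; the two correlations
share the same samples, so this is an approximation (recorded as such in
the result metadata).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .inference import compare_correlations

__all__ = ["ModelFit", "RelationshipCall", "fit_model", "classify_relationship", "FORMS"]

FORMS = ("linear", "logarithmic", "exponential", "power")

STRONG_THRESHOLD = 0.7
TIE_TOLERANCE = 0.01


@dataclass(frozen=True)
class ModelFit:
    """One fitted model form: coefficients on the model scale and the
    Pearson r on the linearizing coordinates."""

    form: str
    a: float
    b: float
    r_linearized: float
    n: int

    def predict(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self.form == "linear":
            return self.a * x + self.b
        if self.form == "logarithmic":
            return self.a * np.log(x) + self.b
        if self.form == "exponential":
            return self.a * np.exp(self.b * x)
        return self.a * np.power(x, self.b)


def _linearize(form: str, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    if form == "linear":
        return x, y
    if form == "logarithmic":
        if np.any(x <= 0):
            raise ValueError("logarithmic fit requires positive x")
        return np.log(x), y
    if form == "exponential":
        if np.any(y <= 0):
            raise ValueError("exponential fit requires positive y")
        return x, np.log(y)
    if form == "power":
        if np.any(x <= 0):
            raise ValueError("power fit requires positive x")
        if np.any(y <= 0):
            raise ValueError("power fit requires positive y")
        return np.log(x), np.log(y)
    raise ValueError(f"unknown form {form!r}")


def fit_model(form: str, x, y) -> ModelFit:
    """Fit one model form by OLS on its linearizing coordinates.

    Raises ``ValueError`` for n < 3, for nonpositive values where a log is
    required (naming the offending coordinate), and for zero variance in
    either linearized coordinate.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d arrays of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    u, v = _linearize(form, x, y)
    if np.ptp(u) == 0.0 or np.ptp(v) == 0.0:
        raise ValueError(f"zero variance in linearized coordinates for {form} fit")
    res = stats.linregress(u, v)
    slope, intercept, r = float(res.slope), float(res.intercept), float(res.rvalue)
    if form in ("exponential", "power"):
        a, b = float(np.exp(intercept)), slope
    else:
        a, b = slope, intercept
    return ModelFit(form=form, a=a, b=b, r_linearized=r, n=int(x.size))


_SWITCH_BY_FORM = {
    "linear": "rheostat",
    "logarithmic": "on_switch",
    "exponential": "on_switch",
}


def _switch_label(fit: ModelFit) -> str:
    if fit.form == "power":
        return "off_switch" if fit.b < 0 else "on_switch"
    return _SWITCH_BY_FORM[fit.form]


@dataclass(frozen=True)
class RelationshipCall:
    """Classification of one analyte pair in one cell type."""

    cell_type: str
    x_analyte: str
    y_analyte: str
    best: ModelFit
    fits: dict[str, ModelFit] = field(default_factory=dict)
    inadmissible: tuple[str, ...] = ()
    switch_label: str = "none"
    better_than_linear_p: float | None = None
    p_method: str = "independent_fisher_rtoz"


def classify_relationship(
    x,
    y,
    cell_type: str = "",
    x_analyte: str = "",
    y_analyte: str = "",
    strong_threshold: float = STRONG_THRESHOLD,
    tie_tolerance: float = TIE_TOLERANCE,
    dependent_rtoz: bool = False,
) -> RelationshipCall:
    """Fit all admissible forms and call the relationship for one pair.

    Forms whose positivity precondition fails are skipped (recorded as
    inadmissible), not errored.  The best form maximises |r| on its
    linearizing coordinates; a nonlinear form must beat the linear |r| by
    more than ``tie_tolerance`` to displace it.  ``better_than_linear_p``
    is the two-sided Fisher r-to-z p comparing the best nonlinear |r| with
    the linear |r| (missing when the call is linear).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = ~np.isnan(x) & ~np.isnan(y)
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise ValueError("need at least 3 complete observations")
    fits: dict[str, ModelFit] = {}
    inadmissible: list[str] = []
    for form in FORMS:
        needs_x_pos = form in ("logarithmic", "power")
        needs_y_pos = form in ("exponential", "power")
        if (needs_x_pos and np.any(x <= 0)) or (needs_y_pos and np.any(y <= 0)):
            inadmissible.append(form)
            continue
        fits[form] = fit_model(form, x, y)
    if not fits:
        raise ValueError("no admissible model form for this pair")
    best_form = max(fits, key=lambda f: abs(fits[f].r_linearized))
    if (
        best_form != "linear"
        and "linear" in fits
        and abs(fits[best_form].r_linearized) - abs(fits["linear"].r_linearized)
        <= tie_tolerance
    ):
        best_form = "linear"
    best = fits[best_form]
    label = _switch_label(best) if abs(best.r_linearized) >= strong_threshold else "none"
    p: float | None = None
    method = "independent_fisher_rtoz"
    if best_form != "linear" and "linear" in fits:
        r_lin = abs(fits["linear"].r_linearized)
        r_best = abs(best.r_linearized)
        if r_best >= 1.0 or r_lin >= 1.0:
            # a perfect correlation has an infinite Fisher z; the contrast
            # degenerates to certainty one way or the other
            p = 0.0 if r_best > r_lin else 1.0
        elif dependent_rtoz:
            from .inference import compare_dependent_correlations

            u_lin, v_lin = _linearize("linear", x, y)
            u_best, v_best = _linearize(best_form, x, y)
            # the two fits share coordinate x (or ln x); r23 correlates the
            # two response coordinates
            r23 = abs(float(np.corrcoef(v_lin, v_best)[0, 1]))
            p = compare_dependent_correlations(r_lin, r_best, r23, x.size).p
            method = "dependent_steiger"
        else:
            p = compare_correlations(r_lin, x.size, r_best, x.size).p
    return RelationshipCall(
        cell_type=cell_type,
        x_analyte=x_analyte,
        y_analyte=y_analyte,
        best=best,
        fits=fits,
        inadmissible=tuple(inadmissible),
        switch_label=label,
        better_than_linear_p=p,
        p_method=method,
    )
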