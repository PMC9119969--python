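"""Dye-solubilisation CMC estimation, standard-curve quantitation and LDH release.

The critical micelle concentration (CMC) of an amphiphilic polymer is read
off a dye-solubilisation curve: the difference in probe absorbance (e.g.
DPH at 376 vs 400 nm) plotted against polymer concentration is flat-ish in
the unimeric regime and steepens sharply once micelles form.  The CMC is
the abscissa where straight lines fitted to the two regimes intersect.

Micelle shedding is quantified against a quadratic standard curve of
concentration versus absorbance difference, inverted on its monotone
branch.  LDH cytotoxicity normalises background-subtracted absorbance
between a medium blank and a full-lysis control.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "SolubilisationCurve",
    "CmcEstimator",
    "QuadraticStandardCurve",
    "LdhRecord",
    "FitError",
    "NoIntersectionError",
    "OutOfRangeError",
    "estimate_cmc",
    "fit_standard_curve",
    "invert_standard_curve",
    "ldh_release",
]


class FitError(ValueError):
    """A regression fit is infeasible (too few points, rank deficiency)."""


class NoIntersectionError(RuntimeError):
    """The two fitted lines are parallel or cross outside the data range."""


class OutOfRangeError(ValueError):
    """A quantity falls outside the admissible calibration interval."""


@dataclass
class SolubilisationCurve:
    """Concentration vs absorbance-difference data for one titration."""

    concentration: np.ndarray
    delta_absorbance: np.ndarray
    wavelength_pair: tuple[float, float] = (376.0, 400.0)
    temperature: float = 37.0

    def __post_init__(self) -> None:
        self.concentration = np.asarray(self.concentration, dtype=float)
        self.delta_absorbance = np.asarray(self.delta_absorbance, dtype=float)
        if self.concentration.shape != self.delta_absorbance.shape:
            raise FitError("concentration and delta_absorbance must align")
        if np.any(self.concentration <= 0):
            raise FitError("concentrations must be strictly positive")
        if np.any(np.diff(self.concentration) <= 0):
            raise FitError("concentrations must be sorted strictly ascending")

    def __len__(self) -> int:
        return len(self.concentration)

    @classmethod
    def from_csv(cls, path) -> "SolubilisationCurve":
        df = pd.read_csv(path)
        df = df.sort_values("concentration")
        return cls(
            concentration=df["concentration"].to_numpy(),
            delta_absorbance=df["delta_absorbance"].to_numpy(),
        )


def _ols_line(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Least-squares line; returns (slope, intercept, sse)."""
    xm, ym = x.mean(), y.mean()
    sxx = float(((x - xm) ** 2).sum())
    slope = float(((x - xm) * (y - ym)).sum() / sxx) if sxx > 0 else 0.0
    intercept = float(ym - slope * xm)
    resid = y - (slope * x + intercept)
    return slope, intercept, float(resid @ resid)


def _ols_line_guarded(
    x: np.ndarray, y: np.ndarray, t_crit: float
) -> tuple[float, float, float]:
    """OLS line, collapsed to a flat baseline when the slope is insignificant.

    In the unimeric region of a solubilisation curve the abscissa span is a
    tiny fraction of the concentration range (log-spaced sampling), so the
    fitted slope can be arbitrarily noisy; when |slope| < t_crit * SE the
    segment is refitted as its mean (a flat baseline), which is also the
    physically expected unimeric behaviour.
    """
    slope, intercept, sse = _ols_line(x, y)
    n = len(x)
    if n > 2 and t_crit > 0:
        sxx = float(((x - x.mean()) ** 2).sum())
        if sxx > 0:
            se = np.sqrt(sse / (n - 2) / sxx)
            if abs(slope) < t_crit * se:
                intercept = float(y.mean())
                resid = y - intercept
                return 0.0, intercept, float(resid @ resid)
    return slope, intercept, sse


class CmcEstimator(BaseEstimator, RegressorMixin):
    """Two-line breakpoint estimator for the critical micelle concentration.

    For every contiguous split of the (sorted) curve leaving at least
    ``min_segment`` points per side, least-squares lines are fitted to the
    unimeric (left) and micellar (right) segments; the unimeric line
    collapses to a flat baseline when its slope is statistically
    insignificant (see :func:`_ols_line_guarded`).  Splits are ranked by
    total residual sum of squares and the point estimate is the abscissa of
    the two lines' intersection, taken from the best-ranked split whose
    intersection falls in the gap between its segments (an internally
    consistent split); failing that, the best split with an in-range
    intersection, clipped into its gap.

    On noisy data the point estimate has a heavy-tailed sampling
    distribution — the breakpoint's likelihood is nearly flat above the
    kink — so the reported ``cmc_`` is the median of the point estimator
    over ``n_boot`` residual-bootstrap replicates of the fitted two-segment
    model.  On noiseless data (zero residuals) the bootstrap is a no-op and
    ``cmc_`` equals the exact intersection.

    Parameters
    ----------
    min_segment : int
        Minimum points per segment (default 3, so >= 6 points overall).
    log_x : bool
        Fit in log10 concentration coordinates.  Off by default: the
        solubilisation plot is drawn in linear concentration even when the
        sampling is log-spaced.
    slope_t_crit : float
        Significance multiple for the unimeric-baseline collapse (default
        2.0, the conventional two-sided 5% rule).  Set to 0 to disable.
    n_boot : int
        Residual-bootstrap replicates for the median estimate (default 99).
        Set to 0 for the raw point estimate.
    random_state : int or None
        Seed for the bootstrap stream.

    Attributes
    ----------
    cmc_ : float
        Estimated breakpoint, in the concentration units of the input.
    point_estimate_ : float
        The direct (non-bootstrap) intersection estimate.
    left_line_, right_line_ : (slope, intercept)
        Fitted unimeric and micellar lines of the chosen split (fit coords).
    split_index_ : int
        Number of points assigned to the unimeric segment.
    sse_total_ : float
        Total residual sum of squares of the chosen split.
    diagnostics_ : pandas.DataFrame
        Per-candidate split table (split index, SSE, intersection).
    """

    def __init__(
        self,
        min_segment: int = 3,
        log_x: bool = False,
        slope_t_crit: float = 2.0,
        n_boot: int = 99,
        random_state: int | None = 0,
    ):
        self.min_segment = min_segment
        self.log_x = log_x
        self.slope_t_crit = slope_t_crit
        self.n_boot = n_boot
        self.random_state = random_state

    def _candidates(self, xf: np.ndarray, y: np.ndarray) -> pd.DataFrame:
        rows = []
        for i in range(self.min_segment, len(xf) - self.min_segment + 1):
            m1, c1, sse1 = _ols_line_guarded(xf[:i], y[:i], self.slope_t_crit)
            m2, c2, sse2 = _ols_line(xf[i:], y[i:])
            denom = m2 - m1
            if abs(denom) > 1e-12 * max(abs(m1), abs(m2), 1.0):
                x_star = (c1 - c2) / denom
                in_range = xf[0] <= x_star <= xf[-1]
                in_gap = xf[i - 1] <= x_star <= xf[i]
            else:
                x_star, in_range, in_gap = np.nan, False, False
            rows.append(
                {
                    "split_index": i,
                    "sse": sse1 + sse2,
                    "left_slope": m1,
                    "left_intercept": c1,
                    "right_slope": m2,
                    "right_intercept": c2,
                    "intersection": x_star,
                    "in_range": in_range,
                    "in_gap": in_gap,
                }
            )
        return pd.DataFrame(rows).sort_values("sse", kind="stable").reset_index(drop=True)

    @staticmethod
    def _select(diag: pd.DataFrame, xf: np.ndarray):
        """Best split: prefer in-gap intersections, else clip into the gap."""
        gap_ok = diag[diag["in_gap"]]
        if len(gap_ok):
            best = gap_ok.iloc[0]
            return best, float(best["intersection"])
        in_range = diag[diag["in_range"]]
        if len(in_range):
            best = in_range.iloc[0]
            i = int(best["split_index"])
            return best, float(np.clip(best["intersection"], xf[i - 1], xf[i]))
        return None, None

    def _point_estimate(self, xf: np.ndarray, y: np.ndarray):
        diag = self._candidates(xf, y)
        best, x_star = self._select(diag, xf)
        return diag, best, x_star

    def fit(self, X, y=None) -> "CmcEstimator":
        if isinstance(X, SolubilisationCurve):
            x = X.concentration
            y = X.delta_absorbance
        else:
            x = np.asarray(X, dtype=float).reshape(-1)
            y = np.asarray(y, dtype=float).reshape(-1)
        if len(x) < 2 * self.min_segment:
            raise FitError(
                f"need >= {2 * self.min_segment} points for two segments of "
                f">= {self.min_segment}; got {len(x)}"
            )
        order = np.argsort(x)
        x, y = x[order], y[order]
        xf = np.log10(x) if self.log_x else x

        diag, best, x_star = self._point_estimate(xf, y)
        self.diagnostics_ = diag
        if best is None:
            raise NoIntersectionError(
                "no candidate split yields a line intersection inside the "
                "concentration range (parallel lines or no breakpoint)"
            )
        self.left_line_ = (float(best["left_slope"]), float(best["left_intercept"]))
        self.right_line_ = (float(best["right_slope"]), float(best["right_intercept"]))
        self.split_index_ = int(best["split_index"])
        self.sse_total_ = float(best["sse"])
        self.point_estimate_ = float(10 ** x_star) if self.log_x else float(x_star)

        estimate = x_star
        if self.n_boot > 0:
            # residual bootstrap around the continuous two-segment fit
            design = np.column_stack(
                [np.ones_like(xf), np.minimum(xf - x_star, 0), np.maximum(xf - x_star, 0)]
            )
            beta, *_ = np.linalg.lstsq(design, y, rcond=None)
            fitted = design @ beta
            resid = y - fitted
            resid = resid - resid.mean()
            # exact two-segment data: bootstrap is a no-op, keep the exact root
            if np.max(np.abs(resid)) > 1e-12 * max(np.max(np.abs(y)), 1.0):
                rng = np.random.default_rng(self.random_state)
                draws = []
                for _ in range(self.n_boot):
                    yb = fitted + rng.choice(resid, size=len(resid), replace=True)
                    _, b, xs = self._point_estimate(xf, yb)
                    if b is not None:
                        draws.append(xs)
                if draws:
                    estimate = float(np.median(draws))
        self.cmc_ = float(10 ** estimate) if self.log_x else float(estimate)
        return self

    def predict(self, X) -> np.ndarray:
        """Evaluate the fitted two-line model at concentrations ``X``."""
        check_is_fitted(self, "cmc_")
        x = np.asarray(X, dtype=float).reshape(-1)
        xf = np.log10(x) if self.log_x else x
        bp = np.log10(self.cmc_) if self.log_x else self.cmc_
        m1, c1 = self.left_line_
        m2, c2 = self.right_line_
        return np.where(xf <= bp, m1 * xf + c1, m2 * xf + c2)


class QuadraticStandardCurve(BaseEstimator, RegressorMixin):
    """Quadratic calibration curve ΔA = a·x² + b·x + c with inversion.

    Attributes
    ----------
    coef_ : ndarray (a, b, c)
        Least-squares quadratic coefficients.
    r_squared_ : float
        1 − SSE/SST; 0 by convention (flagged) when the response is constant.
    calibration_range_ : (float, float)
        Span of the calibration concentrations.
    degenerate_ : bool
        True when SST = 0 and the R² convention applied.
    """

    def __init__(self, extrapolation_factor: float = 1.1):
        self.extrapolation_factor = extrapolation_factor

    def fit(self, X, y) -> "QuadraticStandardCurve":
        x = np.asarray(X, dtype=float).reshape(-1)
        y = np.asarray(y, dtype=float).reshape(-1)
        if len(x) < 4:
            raise FitError(f"need >= 4 calibration points, got {len(x)}")
        if len(np.unique(x)) <= 3:
            raise FitError("rank-deficient design: need > 3 distinct concentrations")
        coef = np.polyfit(x, y, 2)
        fitted = np.polyval(coef, x)
        sse = float(np.sum((y - fitted) ** 2))
        sst = float(np.sum((y - y.mean()) ** 2))
        self.degenerate_ = sst == 0.0
        self.r_squared_ = 0.0 if self.degenerate_ else 1.0 - sse / sst
        self.coef_ = coef
        self.calibration_range_ = (float(x.min()), float(x.max()))
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "coef_")
        return np.polyval(self.coef_, np.asarray(X, dtype=float))

    def inverse_predict(self, delta_absorbance) -> np.ndarray:
        """Concentrations whose fitted ΔA equals the given values.

        Solves the quadratic on the monotone branch of the parabola that
        covers the calibration range; roots must lie in
        ``[0, extrapolation_factor * range_max]``.
        """
        check_is_fitted(self, "coef_")
        da = np.atleast_1d(np.asarray(delta_absorbance, dtype=float))
        a, b, c = self.coef_
        lo, hi = self.calibration_range_
        upper = self.extrapolation_factor * hi
        out = np.empty_like(da)
        for k, val in enumerate(da):
            if abs(a) < 1e-300:  # effectively linear
                if b == 0:
                    raise OutOfRangeError("flat curve cannot be inverted")
                root = (val - c) / b
                if not 0 <= root <= upper:
                    raise OutOfRangeError(
                        f"ΔA={val} maps to {root:.4g}, outside [0, {upper:.4g}]"
                    )
                out[k] = root
                continue
            disc = b * b - 4 * a * (c - val)
            if disc < 0:
                raise OutOfRangeError(f"ΔA={val} is beyond the parabola's extremum")
            sq = np.sqrt(disc)
            roots = np.array([(-b - sq) / (2 * a), (-b + sq) / (2 * a)])
            vertex = -b / (2 * a)
            mid = 0.5 * (lo + hi)
            # monotone branch containing the calibration midpoint
            branch = roots[roots >= vertex] if mid >= vertex else roots[roots <= vertex]
            branch = branch[(branch >= 0) & (branch <= upper)]
            if branch.size == 0:
                raise OutOfRangeError(
                    f"ΔA={val} has no root on the calibration branch within "
                    f"[0, {upper:.4g}]"
                )
            out[k] = branch[0]
        return out if np.ndim(delta_absorbance) else float(out[0])


@dataclass
class LdhRecord:
    """One well of an LDH cytotoxicity plate."""

    a490: float
    a690: float
    role: str = "sample"  # sample | medium_blank | lysis_control
    well: str = ""

    @property
    def signal(self) -> float:
        """Background-subtracted absorbance (490 nm minus 690 nm)."""
        return self.a490 - self.a690


# ---------------------------------------------------------------------------
# thin functional wrappers
# ---------------------------------------------------------------------------


def estimate_cmc(curve: SolubilisationCurve, **kwargs) -> CmcEstimator:
    """Fit the two-line breakpoint estimator to a solubilisation curve."""
    return CmcEstimator(**kwargs).fit(curve)


def fit_standard_curve(curve: SolubilisationCurve) -> QuadraticStandardCurve:
    """Least-squares quadratic calibration of ΔA against concentration."""
    return QuadraticStandardCurve().fit(curve.concentration, curve.delta_absorbance)


def invert_standard_curve(sc: QuadraticStandardCurve, delta_absorbance):
    """Concentration(s) corresponding to measured ΔA on the fitted curve."""
    return sc.inverse_predict(delta_absorbance)


def ldh_release(records: Iterable[LdhRecord]) -> pd.DataFrame:
    """Percent LDH release per sample well, normalised between controls.

    ``release = 100 * (s_sample − mean(s_blank)) / (mean(s_lysis) − mean(s_blank))``
    with ``s = A490 − A690``.
    """
    records = list(records)
    blanks = [r.signal for r in records if r.role == "medium_blank"]
    lysis = [r.signal for r in records if r.role == "lysis_control"]
    if not blanks or not lysis:
        raise FitError("need at least one medium_blank and one lysis_control well")
    s_blank = float(np.mean(blanks))
    s_lysis = float(np.mean(lysis))
    if s_lysis <= s_blank:
        raise FitError(
            f"invalid controls: lysis mean {s_lysis:.4g} must exceed blank mean {s_blank:.4g}"
        )
    rows = []
    for r in records:
        if r.role != "sample":
            continue
        rows.append(
            {
                "well": r.well,
                "signal": r.signal,
                "release_pct": 100.0 * (r.signal - s_blank) / (s_lysis - s_blank),
            }
        )
    return pd.DataFrame(rows, columns=["well", "signal", "release_pct"])
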