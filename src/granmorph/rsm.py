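"""Quadratic response-surface models of granule size and process yield.

The central object is the six-term quadratic polynomial in the two wet-
granulation process factors, liquid-to-solid ratio X1 = L/S and impeller
speed X2 = IS (rpm):

    Y = b0 + b1*X1 + b2*X2 + b11*X1**2 + b22*X2**2 + b12*X1*X2

fitted by ordinary least squares in natural (uncoded) units, with a per-term
ANOVA (partial, drop-one sums of squares) and an F-test of the whole model.
The module also ships the published reference coefficient sets for the mean
granule size (mm) and process yield (%) surfaces, which the synthetic
experiment generator uses as its ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from granmorph.errors import DesignError, ValidationError

#: Column order of the quadratic design matrix.
TERM_NAMES = ("const", "ls", "is", "ls^2", "is^2", "ls*is")

#: Human-readable ANOVA term labels, in conventional table order.
ANOVA_TERMS = ("Model", "L/S", "IS", "L/S x IS", "L/S^2", "IS^2")

# Map from ANOVA term label to the design-matrix column it drops.
_TERM_COLUMN = {"L/S": 1, "IS": 2, "L/S^2": 3, "IS^2": 4, "L/S x IS": 5}


@dataclass(frozen=True)
class QuadraticModel:
    """Fitted (or reference) six-term quadratic response surface.

    Coefficients are in natural units: ``b2`` has units of response per rpm,
    ``b22`` response per rpm^2, etc.  ``r_squared`` and the residual
    bookkeeping are ``nan`` for reference models that were not fitted here.
    """

    b0: float
    b1: float
    b2: float
    b11: float
    b22: float
    b12: float
    r_squared: float = float("nan")
    residual_df: int = 0
    residual_ss: float = float("nan")
    stderr: tuple[float, ...] | None = None
    exact_fit: bool = False
    degenerate_r2: bool = False
    source: str = "fit"

    @property
    def coefficients(self) -> np.ndarray:
        """Coefficients in design-matrix order (const, ls, is, ls^2, is^2, ls*is)."""
        return np.array([self.b0, self.b1, self.b2, self.b11, self.b22, self.b12])

    def predict(self, ls, is_rpm) -> np.ndarray:
        """Evaluate the surface at (broadcastable) L/S and impeller-speed values."""
        ls = np.asarray(ls, dtype=float)
        is_rpm = np.asarray(is_rpm, dtype=float)
        return (
            self.b0
            + self.b1 * ls
            + self.b2 * is_rpm
            + self.b11 * ls**2
            + self.b22 * is_rpm**2
            + self.b12 * ls * is_rpm
        )

    def conf_int(self, alpha: float = 0.05) -> np.ndarray:
        """Two-sided (1-alpha) confidence intervals, shape (6, 2).

        Requires a fitted model with stored standard errors and residual df.
        """
        if self.stderr is None or self.residual_df < 1:
            raise ValidationError("confidence intervals require a fitted model")
        t = stats.t.ppf(1.0 - alpha / 2.0, self.residual_df)
        beta = self.coefficients
        se = np.asarray(self.stderr)
        return np.column_stack([beta - t * se, beta + t * se])

    def to_dict(self) -> dict:
        return {
            "coefficients": dict(zip(TERM_NAMES, map(float, self.coefficients))),
            "r_squared": float(self.r_squared),
            "residual_df": int(self.residual_df),
            "residual_ss": float(self.residual_ss),
            "exact_fit": self.exact_fit,
            "source": self.source,
        }


@dataclass(frozen=True)
class AnovaRow:
    term: str
    ss: float
    df: int
    ms: float
    f: float
    p: float
    exact_fit: bool = False


@dataclass(frozen=True)
class LinearFit:
    """Simple least-squares line y = slope * x + intercept."""

    slope: float
    intercept: float
    r_squared: float
    degenerate: bool = False

    def predict(self, x):
        return self.slope * np.asarray(x, dtype=float) + self.intercept


def build_design_matrix(ls, is_rpm) -> np.ndarray:
    """n x 6 quadratic design matrix [1, X1, X2, X1^2, X2^2, X1*X2] in natural units."""
    ls = np.atleast_1d(np.asarray(ls, dtype=float))
    is_rpm = np.atleast_1d(np.asarray(is_rpm, dtype=float))
    if ls.shape != is_rpm.shape:
        raise DesignError("predictor lists must have equal length")
    if ls.size < 6:
        raise DesignError(
            f"quadratic model needs at least 6 design points, got {ls.size}"
        )
    return np.column_stack(
        [np.ones_like(ls), ls, is_rpm, ls**2, is_rpm**2, ls * is_rpm]
    )


def coded_values(x, low: float, high: float) -> np.ndarray:
    """Map natural factor levels onto the coded [-1, 1] interval."""
    if not high > low:
        raise DesignError("coded range requires high > low")
    x = np.asarray(x, dtype=float)
    return (2.0 * x - (high + low)) / (high - low)


def _rank_check(design: np.ndarray) -> None:
    # Column-scale before the rank test so rpm^2 magnitudes do not mask
    # genuine collinearity.
    norms = np.linalg.norm(design, axis=0)
    if np.any(norms == 0):
        bad = [TERM_NAMES[i] for i in np.flatnonzero(norms == 0)]
        raise DesignError(f"design matrix has zero columns: {bad}")
    scaled = design / norms
    if np.linalg.matrix_rank(scaled, tol=1e-10) < design.shape[1]:
        s = np.linalg.svd(scaled, compute_uv=False)
        raise DesignError(
            "design matrix is rank deficient (collinear columns among "
            f"{TERM_NAMES}); singular values {s}"
        )


def fit_quadratic(design: np.ndarray, responses) -> QuadraticModel:
    """Ordinary least-squares fit of the six-term quadratic surface.

    The design matrix is column-scaled internally before solving so that the
    wildly different magnitudes of the rpm and rpm^2 columns do not degrade
    the recovered coefficients; the scaling is undone exactly afterwards.
    """
    design = np.asarray(design, dtype=float)
    y = np.asarray(responses, dtype=float)
    if design.ndim != 2 or design.shape[1] != 6:
        raise DesignError("design must be an n x 6 matrix")
    if y.shape != (design.shape[0],):
        raise DesignError("responses must match the number of design rows")
    _rank_check(design)

    norms = np.linalg.norm(design, axis=0)
    res = sm.OLS(y, design / norms).fit()
    beta = res.params / norms
    stderr = tuple(res.bse / norms)

    resid_ss = float(res.ssr)
    total_ss = float(np.sum((y - y.mean()) ** 2))
    degenerate = total_ss == 0.0
    r2 = float("nan") if degenerate else 1.0 - resid_ss / total_ss
    exact = resid_ss <= 1e-12 * max(total_ss, 1.0)
    return QuadraticModel(
        *map(float, beta),
        r_squared=r2,
        residual_df=design.shape[0] - 6,
        residual_ss=resid_ss,
        stderr=stderr,
        exact_fit=exact,
        degenerate_r2=degenerate,
    )


def anova_quadratic(
    model: QuadraticModel,
    design: np.ndarray,
    responses,
    ss_type: str = "partial",
) -> list[AnovaRow]:
    """Per-term ANOVA for a fitted quadratic surface.

    The Model row tests all five non-constant terms jointly; term rows carry
    partial (drop-one) sums of squares by default, or sequential (type-I)
    sums of squares with ``ss_type='sequential'``.  With a zero residual sum
    of squares (exact fit) F ratios are reported as ``inf`` with p = 0 and
    the ``exact_fit`` flag set.
    """
    if ss_type not in ("partial", "sequential"):
        raise ValidationError(f"unknown ss_type {ss_type!r}")
    design = np.asarray(design, dtype=float)
    y = np.asarray(responses, dtype=float)
    if model.residual_df < 1:
        raise DesignError("ANOVA requires residual degrees of freedom >= 1")

    resid_ss = model.residual_ss
    df_res = model.residual_df
    total_ss = float(np.sum((y - y.mean()) ** 2))
    model_ss = total_ss - resid_ss
    exact = model.exact_fit
    ms_res = resid_ss / df_res

    def f_and_p(ms: float, df_num: int) -> tuple[float, float]:
        if exact or ms_res == 0.0:
            return float("inf"), 0.0
        f = ms / ms_res
        return f, float(stats.f.sf(f, df_num, df_res))

    rows = []
    ms_model = model_ss / 5
    f, p = f_and_p(ms_model, 5)
    rows.append(AnovaRow("Model", model_ss, 5, ms_model, f, p, exact))

    if ss_type == "partial":
        for term in ANOVA_TERMS[1:]:
            j = _TERM_COLUMN[term]
            reduced = np.delete(design, j, axis=1)
            beta, _, _, _ = np.linalg.lstsq(reduced, y, rcond=None)
            ss_term = float(np.sum((y - reduced @ beta) ** 2)) - resid_ss
            ss_term = max(ss_term, 0.0)
            f, p = f_and_p(ss_term, 1)
            rows.append(AnovaRow(term, ss_term, 1, ss_term, f, p, exact))
    else:
        # Sequential: add columns in design order, attribute the SS drop.
        order = [("L/S", 1), ("IS", 2), ("L/S^2", 3), ("IS^2", 4), ("L/S x IS", 5)]
        cols = [0]
        prev_rss = total_ss
        seq: dict[str, float] = {}
        for term, j in order:
            cols.append(j)
            sub = design[:, cols]
            beta, _, _, _ = np.linalg.lstsq(sub, y, rcond=None)
            rss = float(np.sum((y - sub @ beta) ** 2))
            seq[term] = max(prev_rss - rss, 0.0)
            prev_rss = rss
        for term in ANOVA_TERMS[1:]:
            ss_term = seq[term]
            f, p = f_and_p(ss_term, 1)
            rows.append(AnovaRow(term, ss_term, 1, ss_term, f, p, exact))
    return rows


def anova_table(rows: list[AnovaRow]) -> pd.DataFrame:
    """ANOVA rows as a DataFrame in conventional column order."""
    return pd.DataFrame(
        [
            {"term": r.term, "SS": r.ss, "df": r.df, "MS": r.ms, "F": r.f, "p": r.p}
            for r in rows
        ]
    )


def predict_surface(model: QuadraticModel, ls_grid, is_grid) -> pd.DataFrame:
    """Evaluate a quadratic surface on the tensor grid ls_grid x is_grid.

    Returns a long-format frame with columns ``ls_ratio, impeller_rpm,
    prediction``, suitable for contouring.
    """
    ls_grid = np.asarray(ls_grid, dtype=float)
    is_grid = np.asarray(is_grid, dtype=float)
    ll, ii = np.meshgrid(ls_grid, is_grid, indexing="ij")
    zz = model.predict(ll, ii)
    return pd.DataFrame(
        {
            "ls_ratio": ll.ravel(),
            "impeller_rpm": ii.ravel(),
            "prediction": zz.ravel(),
        }
    )


def default_prediction_grid(
    n: int = 101,
    ls_range: tuple[float, float] = (0.70, 1.27),
    is_range: tuple[float, float] = (300.0, 700.0),
) -> tuple[np.ndarray, np.ndarray]:
    """Default contouring grid spanning the experimental factor ranges."""
    return (
        np.linspace(ls_range[0], ls_range[1], n),
        np.linspace(is_range[0], is_range[1], n),
    )


def fit_linear(x, y) -> LinearFit:
    """Simple least-squares regression y = slope * x + intercept.

    A constant response is allowed (slope 0, R^2 flagged degenerate); a
    constant predictor is not.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or x.shape != y.shape:
        raise DesignError("linear fit needs >= 2 paired observations")
    if np.ptp(x) == 0:
        raise DesignError("predictor is constant; slope is undefined")
    if np.ptp(y) == 0:
        return LinearFit(0.0, float(y[0]), float("nan"), degenerate=True)
    res = stats.linregress(x, y)
    return LinearFit(float(res.slope), float(res.intercept), float(res.rvalue**2))


def reference_models() -> dict[str, QuadraticModel]:
    """Published quadratic surfaces for mean granule size (mm) and yield (%).

    Coefficients are carried exactly as printed, in natural units (L/S
    dimensionless, impeller speed in rpm).
    """
    d_mean = QuadraticModel(
        b0=3.22765,
        b1=-6.10009,
        b2=0.000907,
        b11=4.41496,
        b22=1.0458e-6,
        b12=-0.002795,
        r_squared=0.9436,
        source="reference: mean granule size surface",
    )
    yield_pct = QuadraticModel(
        b0=-286.33147,
        b1=425.81688,
        b2=0.228893,
        b11=-146.81044,
        b22=-0.000257,
        b12=0.056508,
        r_squared=0.8905,
        source="reference: process yield surface",
    )
    return {"d_mean": d_mean, "yield": yield_pct}


def reference_anova_tables() -> dict[str, pd.DataFrame]:
    """Published ANOVA tables for the two reference surfaces, as printed.

    Residual SS/df were not published; the residual mean square is
    recoverable (up to printed rounding) as MS_model / F_model.
    """
    d_mean = pd.DataFrame(
        {
            "term": list(ANOVA_TERMS),
            "SS": [8.49, 2.17, 1.16, 0.4514, 1.31, 0.0354],
            "df": [5, 1, 1, 1, 1, 1],
            "MS": [1.70, 2.17, 1.16, 0.4514, 1.31, 0.0354],
            "F": [284.41, 363.35, 194.55, 75.60, 218.61, 5.93],
        }
    )
    yield_pct = pd.DataFrame(
        {
            "term": list(ANOVA_TERMS),
            "SS": [63398.24, 61713.25, 1435.83, 184.50, 1443.32, 2144.73],
            "df": [5, 1, 1, 1, 1, 1],
            "MS": [12679.65, 61713.25, 1435.83, 184.50, 1443.32, 2144.73],
            "F": [138.32, 673.21, 15.66, 2.01, 15.74, 23.40],
        }
    )
    return {"d_mean": d_mean, "yield": yield_pct}
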