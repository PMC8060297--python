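"""Colocalization of spatial gradients across serial sections.

Top-down profiles of several markers, taken from consecutive serial
sections of one sample, are stacked into a position x marker matrix. Simple
and multiple linear regression then quantify how much the markers' spatial
gradients overlap; a polynomial calibration refines the multiple model;
virtual knockout (zeroing one predictor's profile and re-predicting) scores
each factor's direction of effect; and regressing the DAPI profile of
stepped sections on a reference section measures how many serial sections
remain compatible for this kind of analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .quantify import TDProfile

__all__ = [
    "ProfileMatrix",
    "RegressionFit",
    "VKOResult",
    "CompatibilityReport",
    "stack_profiles",
    "simple_regression",
    "multiple_regression",
    "polynomial_refine",
    "virtual_knockout",
    "serial_compatibility",
    "DEFAULT_ALPHA",
]

logger = logging.getLogger(__name__)

#: Significance level used for the spatial-gradient regressions.
DEFAULT_ALPHA = 1e-8


@dataclass
class ProfileMatrix:
    """N positions x M markers of row-mean grey values on a shared axis."""

    markers: list[str]
    values: np.ndarray  # (N, M) float64
    positions_um: np.ndarray  # (N,)
    sample_id: str = ""
    in_section_counts: np.ndarray | None = None  # (N, M) or None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.positions_um = np.asarray(self.positions_um, dtype=np.float64)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.markers):
            raise ValueError(
                f"values must be (N, {len(self.markers)}), got {self.values.shape}"
            )
        if self.positions_um.shape != (self.values.shape[0],):
            raise ValueError("positions_um length must match the number of rows")
        if len(set(self.markers)) != len(self.markers):
            raise ValueError(f"duplicate marker names in {self.markers}")

    def column(self, marker: str) -> np.ndarray:
        return self.values[:, self.markers.index(marker)]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.markers)
        df.insert(0, "um", self.positions_um)
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame, sample_id: str = "") -> "ProfileMatrix":
        cols = [c for c in df.columns if c != "um"]
        pos = df["um"].to_numpy() if "um" in df.columns else np.arange(len(df), dtype=float)
        return cls(markers=cols, values=df[cols].to_numpy(float), positions_um=pos,
                   sample_id=sample_id)


@dataclass
class RegressionFit:
    """An OLS fit of a dependent profile on one or more predictor profiles.

    ``coefficients`` lists the slope for each predictor followed by the
    intercept. ``std_error`` is the residual standard error in grey-value
    units. ``ci99`` rows align with ``coefficients``.
    """

    dependent: str
    predictors: list[str]
    coefficients: np.ndarray  # slopes..., intercept
    R: float
    R2: float
    F: float
    p: float
    ci99: np.ndarray | None  # (k, 2) lower/upper per coefficient
    predicted: np.ndarray
    observed: np.ndarray
    std_error: float
    n: int
    alpha: float = DEFAULT_ALPHA
    polynomial_order: int = 0  # 0 = linear model
    simple_r2: dict[str, float] = field(default_factory=dict)
    row_mask: np.ndarray | None = None  # rows of the source matrix used in the fit

    @property
    def significant(self) -> bool:
        return self.p < self.alpha

    @property
    def slopes(self) -> np.ndarray:
        return self.coefficients[: len(self.predictors)]

    @property
    def intercept(self) -> float:
        return float(self.coefficients[-1])


@dataclass
class VKOResult:
    """Virtual knockout of one predictor in a fitted linear model."""

    factor: str
    baseline_mean_gv: float
    knockout_mean_gv: float
    fold_change: float
    direction: Literal["pro", "anti", "neutral"]


def _profile_values(p) -> np.ndarray:
    if isinstance(p, TDProfile):
        return p.row_means
    return np.asarray(p, dtype=np.float64)


def stack_profiles(
    profiles: Sequence,
    markers: Sequence[str] | None = None,
    relative: bool = False,
    sample_id: str = "",
) -> ProfileMatrix:
    """Assemble equal-length profiles into a position x marker matrix.

    Profiles must already be aligned (serial sections are formatted
    upstream); a length mismatch is an error, not something to resample
    away. By default raw row-mean grey values are stacked so downstream
    knockout fold changes stay in grey-value units; ``relative=True`` stacks
    the %-of-max form instead.
    """
    if markers is None:
        markers = [
            p.marker_name if isinstance(p, TDProfile) and p.marker_name else f"marker_{i}"
            for i, p in enumerate(profiles)
        ]
    markers = list(markers)
    if len(markers) != len(profiles):
        raise ValueError(f"{len(profiles)} profiles but {len(markers)} marker names")
    lengths = [len(_profile_values(p)) for p in profiles]
    if len(set(lengths)) > 1:
        raise ValueError(f"profiles have mismatched lengths {lengths}; align them upstream")
    cols, counts = [], []
    for p in profiles:
        if relative and isinstance(p, TDProfile):
            cols.append(p.rel_pct)
        else:
            cols.append(_profile_values(p))
        counts.append(
            p.in_section_counts if isinstance(p, TDProfile) else np.ones(lengths[0], dtype=np.int64)
        )
    first = profiles[0]
    if isinstance(first, TDProfile):
        positions = first.positions_um
    else:
        positions = np.arange(lengths[0], dtype=float)
    return ProfileMatrix(
        markers=markers,
        values=np.column_stack(cols),
        positions_um=positions,
        sample_id=sample_id,
        in_section_counts=np.column_stack(counts),
    )


def _finish_fit(model, dependent, predictors, alpha, simple_r2=None, row_mask=None) -> RegressionFit:
    res = model.fit()
    # statsmodels puts the constant first; we report slopes first, intercept last
    params = np.r_[res.params[1:], res.params[0]]
    ci = res.conf_int(alpha=0.01)
    ci99 = np.vstack([ci[1:], ci[:1]])
    r2 = float(res.rsquared)
    if len(predictors) == 1:
        r = float(np.sign(params[0]) * np.sqrt(max(r2, 0.0)))
    else:
        r = float(np.sqrt(max(r2, 0.0)))
    fval = float(res.fvalue) if np.isfinite(res.fvalue) else float("inf")
    pval = float(res.f_pvalue) if np.isfinite(res.f_pvalue) else 0.0
    return RegressionFit(
        dependent=dependent,
        predictors=list(predictors),
        coefficients=params,
        R=r,
        R2=r2,
        F=fval,
        p=pval,
        ci99=ci99,
        predicted=np.asarray(res.fittedvalues, dtype=np.float64),
        observed=np.asarray(model.endog, dtype=np.float64),
        std_error=float(np.sqrt(res.mse_resid)) if res.df_resid > 0 else 0.0,
        n=int(res.nobs),
        alpha=alpha,
        simple_r2=simple_r2 or {},
        row_mask=row_mask,
    )


def simple_regression(
    x,
    y,
    alpha: float = DEFAULT_ALPHA,
    x_name: str = "x",
    y_name: str = "y",
) -> RegressionFit:
    """OLS of one profile on another: ``y = a + b x``.

    Reports R (signed like the slope), R^2, F, p, 99% confidence intervals
    for the coefficients and the residual standard error in grey values.
    """
    xv = _profile_values(x)
    yv = _profile_values(y)
    if isinstance(x, TDProfile):
        x_name = x.marker_name or x_name
    if isinstance(y, TDProfile):
        y_name = y.marker_name or y_name
    if xv.shape != yv.shape or xv.ndim != 1:
        raise ValueError(f"x and y must be equal-length 1-D profiles, got {xv.shape}, {yv.shape}")
    if xv.size < 3:
        raise ValueError("need at least 3 positions to regress")
    if np.var(xv) == 0:
        raise ValueError("predictor profile has zero variance")
    model = sm.OLS(yv, sm.add_constant(xv))
    return _finish_fit(model, y_name, [x_name], alpha)


def multiple_regression(
    X: ProfileMatrix,
    dependent: str,
    alpha: float = DEFAULT_ALPHA,
    condition_limit: float = 1e8,
) -> RegressionFit:
    """OLS of one marker's profile on all the others, with intercept.

    Rows where the dependent section has no in-section pixels are dropped
    pairwise (and logged). Near-perfect collinearity between predictors is
    rejected, naming the offending pair. The fit also carries each
    predictor's single-predictor R^2 (``simple_r2``) for the bar-chart-style
    comparison of individual correlations.
    """
    if dependent not in X.markers:
        raise ValueError(f"dependent {dependent!r} not among markers {X.markers}")
    predictors = [m for m in X.markers if m != dependent]
    y = X.column(dependent)
    Z = np.column_stack([X.column(m) for m in predictors])
    keep = np.ones(len(y), dtype=bool)
    if X.in_section_counts is not None:
        dep_counts = X.in_section_counts[:, X.markers.index(dependent)]
        keep = dep_counts > 0
        dropped = int((~keep).sum())
        if dropped:
            logger.info("dropping %d rows with no in-section pixels in %s", dropped, dependent)
    y, Z = y[keep], Z[keep]
    n, m = Z.shape
    if n <= m + 1:
        raise ValueError(f"need more positions ({n}) than predictors + 1 ({m + 1})")
    # reject (near-)perfect collinearity, naming the worst pair
    if m > 1:
        cc = np.corrcoef(Z, rowvar=False)
        np.fill_diagonal(cc, 0.0)
        i, j = np.unravel_index(np.nanargmax(np.abs(cc)), cc.shape)
        design = (Z - Z.mean(0)) / np.where(Z.std(0) > 0, Z.std(0), 1.0)
        if abs(cc[i, j]) > 1 - 1e-10 or np.linalg.cond(design) > condition_limit:
            raise ValueError(
                f"predictors {predictors[i]!r} and {predictors[j]!r} are collinear "
                f"(|r| = {abs(cc[i, j]):.6f})"
            )
    simple_r2 = {}
    for k, name in enumerate(predictors):
        if np.var(Z[:, k]) == 0:
            raise ValueError(f"predictor {name!r} has zero variance")
        r = stats.pearsonr(Z[:, k], y).statistic if np.var(y) > 0 else 0.0
        simple_r2[name] = float(r * r)
    model = sm.OLS(y, sm.add_constant(Z))
    return _finish_fit(model, dependent, predictors, alpha, simple_r2=simple_r2, row_mask=keep)


def polynomial_refine(fit: RegressionFit, order: int = 6) -> RegressionFit:
    """Refine a linear fit with a polynomial calibration curve.

    Fits a polynomial of the given order mapping the linear model's
    predicted values to the observed dependent profile and reports the
    refined R and R^2. Because the identity map is itself a first-order
    polynomial, the refined R^2 can never fall below the linear one.
    """
    if order < 1:
        raise ValueError(f"polynomial order must be >= 1, got {order}")
    n = fit.predicted.size
    if order >= n:
        raise ValueError(f"polynomial order {order} must be below the number of positions {n}")
    poly = np.polynomial.Polynomial.fit(fit.predicted, fit.observed, deg=order)
    refined = poly(fit.predicted)
    sst = float(((fit.observed - fit.observed.mean()) ** 2).sum())
    ssr = float(((fit.observed - refined) ** 2).sum())
    r2 = 1.0 - ssr / sst if sst > 0 else 1.0
    r2 = min(max(r2, fit.R2), 1.0)  # guard against round-off only
    dof = n - (order + 1)
    if r2 < 1.0 and dof > 0:
        fval = (r2 / order) / ((1.0 - r2) / dof)
        pval = float(stats.f.sf(fval, order, dof))
    else:
        fval, pval = float("inf"), 0.0
    return RegressionFit(
        dependent=fit.dependent,
        predictors=fit.predictors,
        coefficients=poly.convert().coef[::-1],  # highest order first
        R=float(np.sqrt(r2)),
        R2=float(r2),
        F=fval,
        p=pval,
        ci99=None,
        predicted=refined,
        observed=fit.observed,
        std_error=float(np.sqrt(ssr / dof)) if dof > 0 else 0.0,
        n=n,
        alpha=fit.alpha,
        polynomial_order=order,
        simple_r2=dict(fit.simple_r2),
    )


def virtual_knockout(fit: RegressionFit, X: ProfileMatrix, factor: str) -> VKOResult:
    """Zero one predictor's profile and re-predict the dependent profile.

    The factor's column is replaced with zeros, the fitted linear
    coefficients re-applied, and the mean predicted grey value compared with
    the baseline prediction. fold_change = knockout / baseline; a factor
    whose removal lowers the prediction acted "pro" (it was driving the
    dependent signal up), one whose removal raises it acted "anti".
    """
    if fit.polynomial_order != 0:
        raise ValueError("virtual knockout requires the linear model, not a polynomial refinement")
    if factor not in fit.predictors:
        raise ValueError(f"factor {factor!r} not among fitted predictors {fit.predictors}")
    cols = np.column_stack([X.column(m) for m in fit.predictors]).astype(np.float64)
    if fit.row_mask is not None and cols.shape[0] == fit.row_mask.size:
        cols = cols[fit.row_mask]
    if cols.shape[0] != fit.predicted.size:
        raise ValueError(
            f"profile matrix has {cols.shape[0]} rows but the fit used {fit.predicted.size}"
        )
    baseline = cols @ fit.slopes + fit.intercept
    ko_cols = cols.copy()
    ko_cols[:, fit.predictors.index(factor)] = 0.0
    knockout = ko_cols @ fit.slopes + fit.intercept
    base_mean = float(baseline.mean())
    ko_mean = float(knockout.mean())
    if base_mean <= 0 or ko_mean <= 0:
        raise ValueError(
            f"mean predicted grey values must be positive for a fold change "
            f"(baseline {base_mean:.4g}, knockout {ko_mean:.4g})"
        )
    fold = ko_mean / base_mean
    if abs(fold - 1.0) <= 1e-9:
        direction = "neutral"
    elif fold < 1.0:
        direction = "pro"
    else:
        direction = "anti"
    return VKOResult(
        factor=factor,
        baseline_mean_gv=base_mean,
        knockout_mean_gv=ko_mean,
        fold_change=fold,
        direction=direction,
    )


@dataclass
class CompatibilityReport:
    """Serial-section compatibility table (reference vs stepped sections)."""

    sections: list[int]
    fits: list[RegressionFit]
    ref_index: int

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for sec, fit in zip(self.sections, self.fits):
            rows.append(
                {
                    "section": "REF" if sec == self.ref_index else str(sec),
                    "r2": fit.R2,
                    "std_error": fit.std_error,
                    "coefficient": float(fit.slopes[0]),
                    "ci99_lower": float(fit.ci99[0, 0]),
                    "ci99_upper": float(fit.ci99[0, 1]),
                    "f_value": fit.F,
                    "p": fit.p,
                    "significant": fit.significant,
                }
            )
        return pd.DataFrame(rows)


def serial_compatibility(
    dapi_profiles: Sequence[TDProfile],
    ref_index: int = 0,
    step: int = 5,
    alpha: float = DEFAULT_ALPHA,
) -> CompatibilityReport:
    """How far down a serial stack sections stay shape-compatible.

    Regresses the reference section's DAPI profile (dependent) on the
    profile of every ``step``-th section, starting with the reference
    itself (the auto-correlation row with R^2 = 1). Shape drift along the
    stack shows up as decaying R^2.
    """
    if len(dapi_profiles) < 2:
        raise ValueError("need at least two profiles")
    if not 0 <= ref_index < len(dapi_profiles):
        raise ValueError(f"ref_index {ref_index} out of range")
    if step < 1:
        raise ValueError(f"step must be >= 1, got {step}")
    lengths = {len(p) for p in dapi_profiles}
    if len(lengths) > 1:
        raise ValueError(f"profiles have mismatched lengths {sorted(lengths)}")
    ref = dapi_profiles[ref_index]
    sections = [ref_index] + list(range(ref_index + step, len(dapi_profiles), step))
    fits = []
    for sec in sections:
        fits.append(
            simple_regression(
                dapi_profiles[sec],
                ref,
                alpha=alpha,
                x_name=f"section_{sec}",
                y_name=f"section_{ref_index}",
            )
        )
    return CompatibilityReport(sections=sections, fits=fits, ref_index=ref_index)
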