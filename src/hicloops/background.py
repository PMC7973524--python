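"""Per-diagonal Weibull background model and pixel significance.

The contact frequency of Hi-C pixels at a fixed genomic separation
(one matrix diagonal) is modelled with a two-parameter Weibull distribution
(shape *k*, scale *λ*, location fixed at 0), which fits distance-stratified
contact distributions better than normal, log-normal or gamma alternatives.
For each pixel the p-value is the survival probability of observing an
equally or more intense pixel under its diagonal's fitted model,

    p(x) = exp(-(x / λ_d) ** k_d),

and Benjamini–Hochberg correction within each diagonal yields q-values.
Optionally, q-values are rescaled by the chromosome's distance-decay
("scaling") profile: the per-diagonal mean contact frequency normalised to
the first diagonal of a selected range gives coefficients (first entry 1)
by which q-values on each diagonal are divided, relaxing the threshold at
large distances where contacts are sparse.

Fitting details:

* Values above the upper ``fit_quantile`` of a diagonal (preset parameter
  ``q``, default 0.95) are excluded from the fit — bright loop pixels must
  not inflate the background — but still receive p-values.
* Zero pixels are excluded from fitting by default (``include_zeros``
  overrides) and always receive p = 1: a zero can never be evidence of
  enriched contact, and structural zeros from unmappable regions would
  otherwise distort the fit.
* Diagonals with fewer than ``min_fit_size`` usable values (default 50) are
  left unmodelled; all their pixels get p = 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .matrix import ContactMatrix, DiagonalValues, MatrixConfigError, extract_diagonal

__all__ = [
    "WeibullParams",
    "WeibullFitError",
    "ScalingCoefficients",
    "SignificanceResult",
    "MIN_FIT_SIZE",
    "fit_weibull",
    "survival_pvalue",
    "bh_correct",
    "scaling_coefficients",
    "adjust_by_scale",
    "significant_pixel_mask",
    "fit_diagnostics",
    "diagnostics_table",
]

#: Minimum number of usable pixels for a per-diagonal fit.
MIN_FIT_SIZE = 50


class WeibullFitError(ValueError):
    """Raised when a diagonal has too few or degenerate values to model."""


@dataclass(frozen=True)
class WeibullParams:
    """Fitted background model of one diagonal."""

    d: int
    shape: float
    scale: float
    loc: float = 0.0
    n_fit: int = 0
    fit_quantile: float = 1.0

    def __post_init__(self) -> None:
        if not (self.shape > 0 and self.scale > 0):
            raise ValueError("Weibull shape and scale must be positive")


def fit_weibull(
    values: DiagonalValues,
    fit_quantile: float = 0.95,
    include_zeros: bool = False,
    min_fit_size: int = MIN_FIT_SIZE,
) -> WeibullParams:
    """Maximum-likelihood two-parameter Weibull fit to one diagonal.

    Parameters
    ----------
    values
        Diagonal pixel intensities with validity masks.
    fit_quantile
        Upper quantile of the retained values kept for fitting; values above
        it are trimmed as putative signal (loop) pixels.
    include_zeros
        Include mappable zero pixels in the fit (default: excluded).
    min_fit_size
        Minimum number of values required after masking and trimming.

    Raises
    ------
    WeibullFitError
        If the diagonal cannot support a fit; the caller must treat the
        diagonal as unmodelled (its pixels receive p = 1).
    """
    if not 0 < fit_quantile <= 1:
        raise ValueError("fit_quantile must be in (0, 1]")
    mask = values.mappable if include_zeros else values.valid
    data = values.values[mask]
    if fit_quantile < 1.0 and data.size:
        data = data[data <= np.quantile(data, fit_quantile)]
    if data.size < min_fit_size:
        raise WeibullFitError(
            f"diagonal {values.d}: {data.size} usable values < {min_fit_size}"
        )
    if np.unique(data).size < 2:
        raise WeibullFitError(f"diagonal {values.d}: degenerate (constant) values")
    shape, _, scale = stats.weibull_min.fit(data, floc=0)
    return WeibullParams(
        d=values.d,
        shape=float(shape),
        scale=float(scale),
        n_fit=int(data.size),
        fit_quantile=fit_quantile,
    )


def survival_pvalue(x, params: WeibullParams):
    """P(X >= x) under the fitted Weibull: ``exp(-((x - loc)/scale)**shape)``.

    Vectorised over ``x``; values at or below ``loc`` get p = 1.
    """
    x = np.asarray(x, dtype=float)
    z = np.clip((x - params.loc) / params.scale, 0.0, None)
    p = np.exp(-np.power(z, params.shape))
    p = np.clip(p, 0.0, 1.0)
    return float(p) if p.ndim == 0 else p


def bh_correct(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, preserving input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass(frozen=True)
class ScalingCoefficients:
    """Distance-decay normalisation coefficients, 1.0 at the first diagonal."""

    d_start: int
    d_stop: int  # exclusive
    coeffs: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.coeffs, dtype=float)
        if c.size != self.d_stop - self.d_start:
            raise ValueError("coefficient vector does not span the range")
        if c.size and not np.isclose(c[0], 1.0):
            raise ValueError("first coefficient must be 1")
        if np.any(c <= 0):
            raise ValueError("coefficients must be positive")

    def coeff(self, d: int) -> float:
        """Coefficient for diagonal ``d``; 1.0 outside the selected range."""
        if self.d_start <= d < self.d_stop:
            return float(self.coeffs[d - self.d_start])
        return 1.0


def scaling_coefficients(
    cm: ContactMatrix, d_start: int = 1, d_stop: int | None = None
) -> ScalingCoefficients:
    """Per-diagonal mean contact frequency normalised to the first diagonal
    of the range ``[d_start, d_stop)``."""
    if d_stop is None:
        d_stop = cm.n_bins
    if not 0 <= d_start < d_stop <= cm.n_bins:
        raise ValueError(f"invalid diagonal range [{d_start}, {d_stop})")
    means = np.empty(d_stop - d_start)
    for d in range(d_start, d_stop):
        dv = extract_diagonal(cm, d)
        m = dv.mappable
        means[d - d_start] = dv.values[m].mean() if m.any() else 0.0
    if not means[0] > 0:
        raise MatrixConfigError(
            f"first diagonal of range ({d_start}) has non-positive mean"
        )
    return ScalingCoefficients(d_start, d_stop, means / means[0])


def adjust_by_scale(
    calls: pd.DataFrame, coeffs: ScalingCoefficients
) -> pd.DataFrame:
    """Divide each pixel's q-value by its diagonal's scaling coefficient.

    Returns a copy with ``q_adj = min(1, q / coeff(d))``.
    """
    out = calls.copy()
    d = (out["j"] - out["i"]).to_numpy()
    c = np.array([coeffs.coeff(int(x)) for x in d])
    out["q_adj"] = np.minimum(1.0, out["q"].to_numpy() / c)
    return out


@dataclass
class SignificanceResult:
    """Outcome of the per-diagonal significance scan.

    ``calls`` holds the significant pixels (columns i, j, value, p, q,
    q_adj, significant); ``all_calls`` additionally holds every tested pixel
    when the scan was run with ``return_all=True``.
    """

    calls: pd.DataFrame
    models: dict[int, WeibullParams]
    n_tested: int
    n_significant: int
    unmodeled_diagonals: list[int] = field(default_factory=list)
    all_calls: pd.DataFrame | None = None


_CALL_COLUMNS = ["i", "j", "value", "p", "q", "q_adj", "significant"]


def _empty_calls() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "i": pd.Series(dtype=np.int64),
            "j": pd.Series(dtype=np.int64),
            "value": pd.Series(dtype=float),
            "p": pd.Series(dtype=float),
            "q": pd.Series(dtype=float),
            "q_adj": pd.Series(dtype=float),
            "significant": pd.Series(dtype=bool),
        }
    )


def significant_pixel_mask(
    cm: ContactMatrix,
    fit_quantile: float = 0.95,
    q_threshold: float = 0.1,
    scaling_threshold: float = 0.1,
    adjust: bool = False,
    max_distance: int | None = None,
    min_distance: int | None = None,
    include_zeros: bool = False,
    bh_scope: str = "diagonal",
    scaling_range: tuple[int, int] | None = None,
    min_fit_size: int = MIN_FIT_SIZE,
    return_all: bool = False,
) -> SignificanceResult:
    """Model every diagonal and flag significant pixels.

    Parameters
    ----------
    cm
        Balanced contact matrix.
    fit_quantile, include_zeros, min_fit_size
        Passed to :func:`fit_weibull`.
    q_threshold
        Significance threshold on the q-value when scaling adjustment is off.
    scaling_threshold
        Threshold on the scale-adjusted q-value when ``adjust`` is on.
    adjust
        Apply the distance-decay q-value adjustment.
    max_distance, min_distance
        Genomic separation bounds in bp; defaults: no upper bound, and a
        lower bound of one bin (the self-interaction diagonal is skipped).
    bh_scope
        ``"diagonal"`` (default) corrects within each diagonal;
        ``"matrix"`` corrects across all tested pixels at once.
    scaling_range
        Diagonal range for the scaling coefficients (default: all modelled
        diagonals).

    Notes
    -----
    The BH batch on each diagonal is the set of mappable pixels; zero pixels
    participate with p = 1.  Pixels on unmodelled diagonals get p = q = 1
    and are never significant.
    """
    if bh_scope not in ("diagonal", "matrix"):
        raise ValueError("bh_scope must be 'diagonal' or 'matrix'")
    if not (0 < q_threshold <= 1 and 0 < scaling_threshold <= 1):
        raise ValueError("thresholds must lie in (0, 1]")
    res = cm.resolution
    d_min = 1 if min_distance is None else max(1, int(min_distance // res))
    d_max = cm.n_bins - 1
    if max_distance is not None:
        d_max = min(d_max, int(max_distance // res))

    models: dict[int, WeibullParams] = {}
    unmodeled: list[int] = []
    frames: list[pd.DataFrame] = []
    for d in range(d_min, d_max + 1):
        dv = extract_diagonal(cm, d)
        m = dv.mappable
        if not m.any():
            continue
        try:
            params = fit_weibull(
                dv, fit_quantile, include_zeros, min_fit_size=min_fit_size
            )
        except WeibullFitError:
            unmodeled.append(d)
            continue
        models[d] = params
        vals = dv.values[m]
        p = survival_pvalue(vals, params)
        p = np.where(vals > 0, p, 1.0)  # zeros are never evidence
        k = np.flatnonzero(m)
        frames.append(
            pd.DataFrame(
                {"i": k, "j": k + d, "value": vals, "p": p}
            )
        )

    if not frames:
        empty = _empty_calls()
        return SignificanceResult(
            calls=empty,
            models=models,
            n_tested=0,
            n_significant=0,
            unmodeled_diagonals=unmodeled,
            all_calls=empty if return_all else None,
        )

    calls = pd.concat(frames, ignore_index=True)
    if bh_scope == "diagonal":
        d_of = (calls["j"] - calls["i"]).to_numpy()
        q = np.empty(len(calls))
        for d in np.unique(d_of):
            sel = d_of == d
            q[sel] = bh_correct(calls.loc[sel, "p"].to_numpy())
        calls["q"] = q
    else:
        calls["q"] = bh_correct(calls["p"].to_numpy())

    if adjust:
        if scaling_range is None:
            d_lo = min(models) if models else d_min
            d_hi = (max(models) + 1) if models else d_min + 1
        else:
            d_lo, d_hi = scaling_range
        coeffs = scaling_coefficients(cm, d_lo, d_hi)
        calls = adjust_by_scale(calls, coeffs)
        threshold = scaling_threshold
    else:
        calls["q_adj"] = calls["q"]
        threshold = q_threshold

    calls["significant"] = calls["q_adj"] <= threshold
    sig = calls[calls["significant"]].reset_index(drop=True)
    return SignificanceResult(
        calls=sig,
        models=models,
        n_tested=len(calls),
        n_significant=len(sig),
        unmodeled_diagonals=unmodeled,
        all_calls=calls if return_all else None,
    )


@dataclass(frozen=True)
class FitDiagnostics:
    d: int
    n_fit: int
    ks_distance: float
    ks_pvalue: float


def fit_diagnostics(
    values: DiagonalValues,
    params: WeibullParams,
    include_zeros: bool = False,
) -> FitDiagnostics:
    """Kolmogorov–Smirnov distance between the retained values and the fit.

    Applies the same masking and upper-quantile trimming that produced
    ``params``, so the statistic measures in-sample goodness of fit.
    """
    mask = values.mappable if include_zeros else values.valid
    data = values.values[mask]
    if params.fit_quantile < 1.0 and data.size:
        data = data[data <= np.quantile(data, params.fit_quantile)]
    ks = stats.kstest(
        data, stats.weibull_min(params.shape, loc=params.loc, scale=params.scale).cdf
    )
    return FitDiagnostics(
        d=params.d,
        n_fit=int(data.size),
        ks_distance=float(ks.statistic),
        ks_pvalue=float(ks.pvalue),
    )


def diagnostics_table(
    cm: ContactMatrix,
    models: dict[int, WeibullParams],
    include_zeros: bool = False,
) -> pd.DataFrame:
    """Per-diagonal model parameters and KS fit quality.

    Columns: diagonal, genomic distance (bp), shape, scale, n_fit,
    ks_distance — suitable for a TSV dump and for checking that fit quality
    does not degrade with distance.
    """
    rows = []
    for d, params in sorted(models.items()):
        diag = fit_diagnostics(extract_diagonal(cm, d), params, include_zeros)
        rows.append(
            {
                "diagonal": d,
                "distance_bp": d * cm.resolution,
                "shape": params.shape,
                "scale": params.scale,
                "n_fit": diag.n_fit,
                "ks_distance": diag.ks_distance,
            }
        )
    return pd.DataFrame(rows)
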