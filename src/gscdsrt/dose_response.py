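"""Dose–response scoring: percent inhibition, 4PL fits, AUC/IC50/DSS.

The screening readout is a luminescent viability signal per well. Signals are
scaled to plate controls to give percent inhibition, each drug's five-point
dose series is fitted with a four-parameter logistic (4PL) curve, and the
fitted curve is summarised as a Drug Sensitivity Score (DSS): the closed-form
area of the curve above an activity threshold over the tested log10
concentration window, normalised to a 0–50 scale.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

LN10 = math.log(10.0)

#: Response range (max − min observed inhibition, percentage points) below
#: which a curve is considered flat and not fitted.
DEGENERATE_FLOOR = 5.0


# ---------------------------------------------------------------------------
# The 4PL model
# ---------------------------------------------------------------------------

def logistic4(x, top, bottom, slope, log10_ic50):
    """Percent inhibition at ``x = log10(dose µM)``.

    y(x) = bottom + (top − bottom) / (1 + 10^(slope·(log10(IC50) − x)))

    Increasing in ``x`` for positive slope; y(log10 IC50) = (top+bottom)/2.
    """
    x = np.asarray(x, dtype=float)
    z = slope * (log10_ic50 - x)
    # 1/(1+10^z) computed stably via expit-style branching
    with np.errstate(over="ignore"):
        frac = 1.0 / (1.0 + np.power(10.0, np.clip(z, -300, 300)))
    return bottom + (top - bottom) * frac


@dataclass
class LogisticFit:
    """Fitted 4PL parameters for one drug in one culture.

    ``top``/``bottom`` are percent inhibition asymptotes, ``slope`` the Hill
    coefficient, ``ic50`` in µM. ``degenerate`` marks flat responses that were
    not fitted (they score DSS = 0 downstream).
    """

    top: float
    bottom: float
    slope: float
    ic50: float
    residual_sse: float = float("nan")
    converged: bool = False
    degenerate: bool = False

    @property
    def log10_ic50(self) -> float:
        return math.log10(self.ic50)


@dataclass
class DrugResponse:
    dss: float
    auc: float
    ic50: float
    fit: LogisticFit


# ---------------------------------------------------------------------------
# Control scaling
# ---------------------------------------------------------------------------

def scale_to_controls(plate: pd.DataFrame, mode: str = "dsrt") -> pd.DataFrame:
    """Convert raw well signals to percent inhibition.

    ``plate`` is a long-format table with columns ``drug``, ``dose_uM``,
    ``well_type`` (``drug`` / ``neg_ctrl`` / ``pos_ctrl``) and ``signal``.

    mode ``dsrt``
        inhibition = 100·(neg_mean − signal)/(neg_mean − pos_mean), scaling to
        both the DMSO negative and the benzethonium-chloride positive control.
    mode ``neg_only``
        relative viability = 100·signal/neg_mean, reported as
        inhibition = 100 − viability (DMSO-only normalisation).

    Values outside [0, 100] are preserved, not clipped (clipping would bias
    the fitted asymptotes) and flagged in the ``out_of_range`` column.
    """
    if mode not in ("dsrt", "neg_only"):
        raise ValueError(f"unknown scaling mode {mode!r}")
    neg = plate.loc[plate["well_type"] == "neg_ctrl", "signal"]
    if neg.empty:
        raise ValueError("plate has no negative control wells")
    neg_mean = float(neg.mean())

    drug_wells = plate[plate["well_type"] == "drug"]
    if mode == "dsrt":
        pos = plate.loc[plate["well_type"] == "pos_ctrl", "signal"]
        if pos.empty:
            raise ValueError("dsrt scaling requires positive control wells")
        pos_mean = float(pos.mean())
        if neg_mean <= pos_mean:
            raise ValueError(
                "inverted controls: negative-control mean must exceed "
                f"positive-control mean (neg={neg_mean}, pos={pos_mean})"
            )
        inhibition = 100.0 * (neg_mean - drug_wells["signal"]) / (neg_mean - pos_mean)
    else:
        if neg_mean <= 0:
            raise ValueError("negative-control mean must be positive")
        inhibition = 100.0 - 100.0 * drug_wells["signal"] / neg_mean

    out = drug_wells[["drug", "dose_uM"]].copy()
    out["inhibition"] = inhibition.to_numpy(dtype=float)
    out["out_of_range"] = (out["inhibition"] < 0) | (out["inhibition"] > 100)
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# 4PL fitting
# ---------------------------------------------------------------------------

@dataclass
class FitConfig:
    """Bounds and defaults for the 4PL least-squares fit.

    bottom is fixed at 0 by default (inhibition baseline); top is
    soft-bounded to [0, 120] to tolerate noisy over-inhibition; slope in
    [0.1, 10]; IC50 within [cmin/100, cmax·100]. The initialisation is
    deterministic: top = max observed inhibition, IC50 = dose nearest the
    half-maximal response, slope = 1.
    """

    fix_bottom: bool = True
    top_bounds: tuple[float, float] = (0.0, 120.0)
    bottom_bounds: tuple[float, float] = (0.0, 100.0)
    slope_bounds: tuple[float, float] = (0.1, 10.0)
    ic50_range_factor: float = 100.0
    degenerate_floor: float = DEGENERATE_FLOOR


def fit_logistic4(
    doses: Sequence[float],
    inhibition: Sequence[float],
    config: FitConfig | None = None,
) -> LogisticFit:
    """Least-squares 4PL fit of percent inhibition against log10(dose µM).

    With fewer than 4 distinct doses the parameter count is reduced
    (bottom fixed at 0; at 2 doses the slope is additionally fixed at 1).
    Responses spanning less than ``degenerate_floor`` percentage points are
    not fitted: a degenerate flat fit is returned and scores DSS = 0.
    """
    config = config or FitConfig()
    doses = np.asarray(doses, dtype=float)
    inh = np.asarray(inhibition, dtype=float)
    if doses.shape != inh.shape:
        raise ValueError("doses and inhibition must have equal length")
    mask = np.isfinite(doses) & np.isfinite(inh)
    doses, inh = doses[mask], inh[mask]
    n_distinct = np.unique(doses).size
    if n_distinct < 2:
        raise ValueError("at least 2 distinct doses are required")
    if np.any(doses <= 0):
        raise ValueError("doses must be positive")

    x = np.log10(doses)
    span = float(inh.max() - inh.min())
    if span < config.degenerate_floor:
        return LogisticFit(
            top=float(inh.max()), bottom=float(min(inh.min(), 0.0)), slope=1.0,
            ic50=float(doses.max()), residual_sse=float(np.sum((inh - inh.mean()) ** 2)),
            converged=False, degenerate=True,
        )

    fix_bottom = config.fix_bottom or n_distinct < 4
    fix_slope = n_distinct < 3

    top0 = float(np.clip(inh.max(), *config.top_bounds))
    bottom0 = 0.0 if fix_bottom else float(np.clip(inh.min(), *config.bottom_bounds))
    half = (top0 + bottom0) / 2.0
    l0 = float(x[np.argmin(np.abs(inh - half))])
    l_lo = math.log10(doses.min() / config.ic50_range_factor)
    l_hi = math.log10(doses.max() * config.ic50_range_factor)
    l0 = min(max(l0, l_lo), l_hi)

    # free-parameter vector layout: [top, (bottom), (slope), log10_ic50]
    p0, lo, hi = [top0], [config.top_bounds[0]], [config.top_bounds[1]]
    if not fix_bottom:
        p0.append(bottom0); lo.append(config.bottom_bounds[0]); hi.append(config.bottom_bounds[1])
    if not fix_slope:
        p0.append(1.0); lo.append(config.slope_bounds[0]); hi.append(config.slope_bounds[1])
    p0.append(l0); lo.append(l_lo); hi.append(l_hi)

    def unpack(p):
        i = 0
        top = p[i]; i += 1
        bottom = 0.0
        if not fix_bottom:
            bottom = p[i]; i += 1
        slope = 1.0
        if not fix_slope:
            slope = p[i]; i += 1
        return top, bottom, slope, p[i]

    def residuals(p):
        top, bottom, slope, L = unpack(p)
        return logistic4(x, top, bottom, slope, L) - inh

    def jacobian(p):
        top, bottom, slope, L = unpack(p)
        with np.errstate(over="ignore"):
            frac = 1.0 / (1.0 + np.power(10.0, np.clip(slope * (L - x), -300, 300)))
        dfrac = -frac * (1.0 - frac) * LN10  # ∂σ/∂u with u = s(L−x)·ln10
        cols = [frac]
        if not fix_bottom:
            cols.append(1.0 - frac)
        if not fix_slope:
            cols.append((top - bottom) * dfrac * (L - x))
        cols.append((top - bottom) * dfrac * slope)
        return np.column_stack(cols)

    res = least_squares(
        residuals, np.asarray(p0), jac=jacobian,
        bounds=(np.asarray(lo), np.asarray(hi)),
        method="trf", xtol=1e-13, ftol=1e-13, gtol=1e-13, max_nfev=400,
    )
    sse = float(2.0 * res.cost)
    if 1e-16 < sse < 1e-4:
        # near-perfect fit stalled in a flat valley (steep curve responding
        # only at the edge of the dose window): polish to machine precision
        res = least_squares(
            residuals, res.x, jac=jacobian,
            bounds=(np.asarray(lo), np.asarray(hi)),
            method="trf", xtol=2.3e-16, ftol=2.3e-16, gtol=1e-15,
            max_nfev=4000, x_scale="jac",
        )
    top, bottom, slope, L = unpack(res.x)
    if bottom > top:  # enforce bottom ≤ top on the reported fit
        top, bottom = bottom, top
    return LogisticFit(
        top=float(top), bottom=float(bottom), slope=float(slope),
        ic50=float(10.0 ** L), residual_sse=float(2.0 * res.cost),
        converged=bool(res.status > 0), degenerate=False,
    )


# ---------------------------------------------------------------------------
# DSS
# ---------------------------------------------------------------------------

def _log1p10(z: np.ndarray | float) -> np.ndarray | float:
    """ln(1 + 10^z), overflow-safe."""
    return np.logaddexp(0.0, np.asarray(z, dtype=float) * LN10)


def area_above_threshold(
    fit: LogisticFit, cmin: float, cmax: float, threshold: float
) -> tuple[float, float]:
    """Closed-form ∫ (y(x) − t) dx over the part of [log10 cmin, log10 cmax]
    where the fitted curve exceeds the activity threshold t.

    Returns ``(area, x1)`` where ``x1`` is the lower integration limit (the
    threshold crossing, clamped to the window). Uses the antiderivative
    ∫ 1/(1+10^(s(L−x))) dx = ln(1+10^(s(x−L)))/(s·ln10).
    """
    t = threshold
    top, bottom, s, L = fit.top, fit.bottom, fit.slope, fit.log10_ic50
    xmin, xmax = math.log10(cmin), math.log10(cmax)
    if top <= t:
        return 0.0, xmax
    if bottom >= t:
        x1 = xmin
    else:
        # solve y(x1) = t: 10^(s(L−x1)) = (top−t)/(t−bottom)
        x1 = L - math.log10((top - t) / (t - bottom)) / s
        x1 = min(max(x1, xmin), xmax)
    if x1 >= xmax:
        return 0.0, xmax
    if top == bottom:
        return (top - t) * (xmax - x1), x1
    integral = (bottom - t) * (xmax - x1) + (top - bottom) / (s * LN10) * float(
        _log1p10(s * (xmax - L)) - _log1p10(s * (x1 - L))
    )
    return float(integral), x1


def auc_normalized(fit: LogisticFit, cmin: float, cmax: float) -> float:
    """Closed-form area under the inhibition curve over the full log10
    window, normalised by 100·window so a fully inhibiting drug scores 1."""
    xmin, xmax = math.log10(cmin), math.log10(cmax)
    top, bottom, s, L = fit.top, fit.bottom, fit.slope, fit.log10_ic50
    if top == bottom:
        integral = top * (xmax - xmin)
    else:
        integral = bottom * (xmax - xmin) + (top - bottom) / (s * LN10) * float(
            _log1p10(s * (xmax - L)) - _log1p10(s * (xmin - L))
        )
    return float(integral) / (100.0 * (xmax - xmin))


def compute_dss(
    fit: LogisticFit,
    cmin: float,
    cmax: float,
    threshold: float = 10.0,
    variant: str = "dss2",
) -> DrugResponse:
    """Drug Sensitivity Score of a fitted curve over [cmin, cmax] µM.

    With A the closed-form area above the threshold t and Δx the full log10
    window:

    * ``dss1`` = 100·A / ((100 − t)·Δx) — normalised area, 0–100 scale;
    * ``dss2`` = dss1 / log10(top) — penalises partial-efficacy curves and
      rescales to 0–50 (default);
    * ``dss3`` = dss2 · (xmax − x1)/Δx — further weights by the fraction of
      the window above threshold.

    Degenerate fits and curves whose top asymptote does not exceed the
    threshold score 0.
    """
    if not (0.0 <= threshold < 100.0):
        raise ValueError("threshold must be in [0, 100)")
    if not cmin < cmax:
        raise ValueError("cmin must be < cmax")
    if variant not in ("dss1", "dss2", "dss3"):
        raise ValueError(f"unknown DSS variant {variant!r}")

    auc = auc_normalized(fit, cmin, cmax)
    if fit.degenerate or fit.top <= threshold:
        return DrugResponse(dss=0.0, auc=auc, ic50=fit.ic50, fit=fit)

    xmin, xmax = math.log10(cmin), math.log10(cmax)
    area, x1 = area_above_threshold(fit, cmin, cmax, threshold)
    if area <= 0.0:
        return DrugResponse(dss=0.0, auc=auc, ic50=fit.ic50, fit=fit)
    dss = 100.0 * area / ((100.0 - threshold) * (xmax - xmin))
    if variant in ("dss2", "dss3"):
        if fit.top <= 1.0:
            dss = 0.0
        else:
            dss /= math.log10(fit.top)
    if variant == "dss3":
        dss *= (xmax - x1) / (xmax - xmin)
    return DrugResponse(dss=float(dss), auc=auc, ic50=fit.ic50, fit=fit)


# ---------------------------------------------------------------------------
# Whole-screen driver
# ---------------------------------------------------------------------------

@dataclass
class ScreenResult:
    """Per-culture × per-drug DSS with companion AUC and IC50 matrices and
    retained fit diagnostics."""

    dss: pd.DataFrame
    auc: pd.DataFrame
    ic50: pd.DataFrame
    fits: dict  # (culture, drug) -> LogisticFit


def screen_to_dss(
    plates: Mapping[str, pd.DataFrame],
    dose_ranges: Mapping[str, tuple[float, float]] | None = None,
    mode: str = "dsrt",
    threshold: float = 10.0,
    variant: str = "dss2",
    fit_config: FitConfig | None = None,
) -> ScreenResult:
    """Fit every culture × drug dose series and assemble DSS/AUC/IC50 matrices.

    ``plates`` maps culture id → long-format plate table. ``dose_ranges``
    optionally fixes the DSS integration window per drug; by default each
    drug's tested min/max dose is used. Missing culture × drug cells stay
    missing (no imputation). Output rows/columns are sorted so the result is
    invariant to input ordering.
    """
    cultures = list(plates)
    if len(set(cultures)) != len(cultures):
        raise ValueError("duplicate culture ids")

    records: dict[tuple[str, str], DrugResponse] = {}
    all_drugs: set[str] = set()
    for culture in sorted(cultures):
        inh_table = scale_to_controls(plates[culture], mode=mode)
        for drug, sub in inh_table.groupby("drug", sort=True):
            all_drugs.add(str(drug))
            doses = sub["dose_uM"].to_numpy(dtype=float)
            if np.unique(doses).size < 2:
                warnings.warn(f"{culture}/{drug}: <2 distinct doses, skipped")
                continue
            fit = fit_logistic4(doses, sub["inhibition"].to_numpy(dtype=float), fit_config)
            if dose_ranges and str(drug) in dose_ranges:
                cmin, cmax = dose_ranges[str(drug)]
            else:
                cmin, cmax = float(doses.min()), float(doses.max())
            records[(culture, str(drug))] = compute_dss(
                fit, cmin, cmax, threshold=threshold, variant=variant
            )

    idx = sorted(cultures)
    cols = sorted(all_drugs)
    dss = pd.DataFrame(np.nan, index=idx, columns=cols)
    auc = pd.DataFrame(np.nan, index=idx, columns=cols)
    ic50 = pd.DataFrame(np.nan, index=idx, columns=cols)
    fits: dict[tuple[str, str], LogisticFit] = {}
    for (culture, drug), resp in records.items():
        dss.loc[culture, drug] = resp.dss
        auc.loc[culture, drug] = resp.auc
        ic50.loc[culture, drug] = resp.ic50
        fits[(culture, drug)] = resp.fit
    dss.index.name = auc.index.name = ic50.index.name = "culture"
    return ScreenResult(dss=dss, auc=auc, ic50=ic50, fits=fits)
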