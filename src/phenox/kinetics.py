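"""Kinetic feature extraction from phenazine-oxidation time courses.

Reduced PCA is fluorescent, so oxidation shows up as fluorescence decay.
The analysis pipeline is: fit a locally weighted scatterplot smoother
(LOWESS, local linear fits with tricube weights) to each well, take the
oxidation rate as minus the local slope, and report

* the maximum oxidation rate and the time at which it occurs (negative
  rates mean the well was net-reducing its PCA);
* the time at which a chosen fraction of the initially reduced PCA has
  been oxidized (default 50%), or the sentinel :data:`NOT_DETECTED` if
  the threshold is never crossed within the record;
* a sensitivity scan of both metrics over the LOWESS window fraction —
  the default fraction of 0.05 sits on the stability plateau while using
  a minimal window.

The local linear fit is implemented here directly (rather than through a
generic smoother) because the derivative of the fit is itself the rate
estimate: each window's fitted slope is retained alongside the fitted
value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


class _NotDetected:
    """Sentinel for wells that never reach the oxidation threshold."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:
        return "N.D."


#: Distinct sentinel (never 0, never the final assay time).
NOT_DETECTED = _NotDetected()


class ParameterError(ValueError):
    """Invalid smoothing or metric parameters."""


class BaselineError(ValueError):
    """Curve baseline is unusable (non-positive)."""


@dataclass(frozen=True)
class OxidationCurve:
    """One well's fluorescence time series (time in hours)."""

    time_h: np.ndarray
    fluorescence: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.time_h, dtype=float)
        f = np.asarray(self.fluorescence, dtype=float)
        keep = np.isfinite(t) & np.isfinite(f)
        dropped = int(len(t) - keep.sum())
        if dropped:
            logger.warning("dropping %d non-finite point(s) from curve", dropped)
            t, f = t[keep], f[keep]
        if len(t) < 3:
            raise ParameterError("curve needs at least 3 finite points")
        if len(t) != len(f):
            raise ParameterError("time and fluorescence lengths differ")
        if np.any(np.diff(t) <= 0):
            raise ParameterError("time must be strictly increasing")
        if np.any(f < 0):
            raise ParameterError("fluorescence must be non-negative")
        object.__setattr__(self, "time_h", t)
        object.__setattr__(self, "fluorescence", f)

    def __len__(self) -> int:
        return len(self.time_h)


@dataclass(frozen=True)
class LowessFit:
    """Smoothed values and local slopes on the observed grid."""

    fraction: float
    iterations: int
    time_h: np.ndarray
    smoothed: np.ndarray
    slopes: np.ndarray


def _neighbor_window(t: np.ndarray, i: int, k: int) -> np.ndarray:
    """Indices of the k time-nearest neighbors of point i (contiguous on a
    sorted grid); ties broken toward earlier time points."""
    n = len(t)
    lo, hi = i, i + 1
    while hi - lo < k:
        left_gap = t[i] - t[lo - 1] if lo > 0 else np.inf
        right_gap = t[hi] - t[i] if hi < n else np.inf
        if left_gap <= right_gap:  # tie -> earlier point
            lo -= 1
        else:
            hi += 1
    return np.arange(lo, hi)


def _tricube(u: np.ndarray) -> np.ndarray:
    w = np.clip(1.0 - np.abs(u) ** 3, 0.0, None) ** 3
    return w


def lowess_smooth(
    curve: OxidationCurve,
    fraction: float = 0.05,
    iterations: int = 0,
) -> LowessFit:
    """Local linear LOWESS fit returning fitted values and slopes.

    For each observation the ``ceil(fraction * N)`` time-nearest points
    are fit by weighted least squares with tricube weights on distance
    scaled by the window span; ``iterations`` extra robustness passes
    down-weight large residuals by the bisquare rule.
    """
    if not 0.0 < fraction <= 1.0:
        raise ParameterError("fraction must lie in (0, 1]")
    t, f = curve.time_h, curve.fluorescence
    n = len(t)
    k = int(np.ceil(fraction * n))
    if k < 2:
        raise ParameterError(
            f"fraction {fraction} gives {k} neighbor(s) for N={n}; need >= 2"
        )

    robust = np.ones(n)
    smoothed = np.empty(n)
    slopes = np.empty(n)
    for _pass in range(iterations + 1):
        for i in range(n):
            idx = _neighbor_window(t, i, k)
            dt = t[idx] - t[i]
            span = np.max(np.abs(dt))
            w = _tricube(dt / span) if span > 0 else np.ones(len(idx))
            w = w * robust[idx]
            if w.sum() <= 0 or np.count_nonzero(w) < 2:
                w = robust[idx] if robust[idx].sum() > 0 else np.ones(len(idx))
            sw = w.sum()
            xm = (w * dt).sum() / sw
            ym = (w * f[idx]).sum() / sw
            sxx = (w * (dt - xm) ** 2).sum()
            if sxx <= 0:
                slopes[i] = 0.0
                smoothed[i] = ym
            else:
                b = (w * (dt - xm) * (f[idx] - ym)).sum() / sxx
                slopes[i] = b
                smoothed[i] = ym - b * xm  # intercept at dt = 0
        if _pass < iterations:
            resid = f - smoothed
            s = np.median(np.abs(resid))
            if s <= 0:
                break
            robust = np.clip(1.0 - (resid / (6.0 * s)) ** 2, 0.0, None) ** 2
    return LowessFit(fraction, iterations, t, smoothed, slopes)


def oxidation_rate_series(fit: LowessFit) -> np.ndarray:
    """Oxidation rate = minus the local slope of smoothed fluorescence
    (positive while PCA is being oxidized)."""
    return -fit.slopes


@dataclass(frozen=True)
class KineticsResult:
    """Per-well kinetic metrics."""

    max_oxidation_rate: float
    t_at_max_rate: float
    t_half: float | _NotDetected
    baseline: float
    fraction: float

    @property
    def t_half_detected(self) -> bool:
        return self.t_half is not NOT_DETECTED


def extract_metrics(
    curve: OxidationCurve,
    fraction: float = 0.05,
    threshold: float = 0.5,
    baseline_points: int = 3,
    iterations: int = 0,
) -> KineticsResult:
    """LOWESS-based metrics for one well.

    The 100%-reduced anchor is the mean of the first ``baseline_points``
    smoothed values; the fraction oxidized is ``1 - smoothed/baseline``
    and ``t_half`` is the first (linearly interpolated) crossing of
    ``threshold``.  Wells that never cross report :data:`NOT_DETECTED`.
    """
    if not 0.0 < threshold < 1.0:
        raise ParameterError("threshold must lie in (0, 1)")
    if baseline_points < 1:
        raise ParameterError("baseline_points must be >= 1")
    fit = lowess_smooth(curve, fraction=fraction, iterations=iterations)
    baseline = float(np.mean(fit.smoothed[:baseline_points]))
    if baseline <= 0:
        raise BaselineError("baseline fluorescence is non-positive")
    rates = oxidation_rate_series(fit)
    i_max = int(np.argmax(rates))
    frac_ox = 1.0 - fit.smoothed / baseline
    t_half: float | _NotDetected = NOT_DETECTED
    above = frac_ox >= threshold
    if above.any():
        j = int(np.argmax(above))
        if j == 0:
            t_half = float(fit.time_h[0])
        else:
            f0, f1 = frac_ox[j - 1], frac_ox[j]
            t0, t1 = fit.time_h[j - 1], fit.time_h[j]
            t_half = float(t0 + (threshold - f0) / (f1 - f0) * (t1 - t0))
    return KineticsResult(
        max_oxidation_rate=float(rates[i_max]),
        t_at_max_rate=float(fit.time_h[i_max]),
        t_half=t_half,
        baseline=baseline,
        fraction=fraction,
    )


def scan_fraction(
    curve: OxidationCurve,
    fractions,
    threshold: float = 0.5,
    baseline_points: int = 3,
) -> pd.DataFrame:
    """Metric sensitivity to the LOWESS window fraction.

    One row per fraction; per-fraction failures are recorded in the
    ``error`` column instead of aborting the scan.
    """
    rows = []
    for frac in fractions:
        row = {"fraction": float(frac), "max_rate": np.nan, "t_at_max": np.nan,
               "t_half": np.nan, "t_half_detected": False, "error": ""}
        try:
            res = extract_metrics(curve, fraction=frac, threshold=threshold,
                                  baseline_points=baseline_points)
            row.update(
                max_rate=res.max_oxidation_rate,
                t_at_max=res.t_at_max_rate,
                t_half=(np.nan if res.t_half is NOT_DETECTED else res.t_half),
                t_half_detected=res.t_half is not NOT_DETECTED,
            )
        except (ParameterError, BaselineError) as exc:
            row["error"] = str(exc)
        rows.append(row)
    return pd.DataFrame(rows)


def summarize_replicates(
    plate: pd.DataFrame,
    fraction: float = 0.05,
    threshold: float = 0.5,
    baseline_points: int = 3,
) -> pd.DataFrame:
    """Per-biological-replicate metrics from a tidy plate table.

    Metrics are computed per well; technical replicates are then averaged
    into their biological replicate, which is the unit carried forward to
    statistics.  ``t_half`` is averaged only when every contributing well
    detected a crossing; otherwise the biological replicate reports not
    detected.  Wells with unusable baselines are excluded with a logged
    count.
    """
    required = {"time_h", "well", "strain", "replicate_id", "replicate_type",
                "fluorescence"}
    missing = required - set(plate.columns)
    if missing:
        raise ParameterError(f"plate table missing column(s): {sorted(missing)}")
    per_well = []
    skipped = 0
    for (well, strain, rep, rtype), grp in plate.groupby(
        ["well", "strain", "replicate_id", "replicate_type"], sort=False
    ):
        grp = grp.sort_values("time_h")
        try:
            curve = OxidationCurve(grp["time_h"].to_numpy(),
                                   grp["fluorescence"].to_numpy())
            res = extract_metrics(curve, fraction=fraction, threshold=threshold,
                                  baseline_points=baseline_points)
        except (ParameterError, BaselineError):
            skipped += 1
            continue
        bio_id = rep.split("-")[0] if isinstance(rep, str) else rep
        per_well.append({
            "strain": strain, "bio_replicate": bio_id, "well": well,
            "replicate_type": rtype,
            "max_rate": res.max_oxidation_rate,
            "t_at_max": res.t_at_max_rate,
            "t_half": (np.nan if res.t_half is NOT_DETECTED else res.t_half),
            "t_half_detected": res.t_half is not NOT_DETECTED,
        })
    if skipped:
        logger.warning("summarize_replicates: excluded %d unusable well(s)", skipped)
    wells = pd.DataFrame(per_well)
    if wells.empty:
        return wells
    out = (
        wells.groupby(["strain", "bio_replicate"], sort=False)
        .agg(
            max_rate=("max_rate", "mean"),
            t_at_max=("t_at_max", "mean"),
            t_half=("t_half", "mean"),
            t_half_detected=("t_half_detected", "all"),
            n_technical=("well", "size"),
        )
        .reset_index()
    )
    out.loc[~out["t_half_detected"], "t_half"] = np.nan
    return out


def integrate_current(
    time_h: np.ndarray, current_uA: np.ndarray
) -> tuple[float, float]:
    """Cumulative charge and PCA-equivalents from a current trace.

    Trapezoidal integration; uA.h -> coulombs via 3.6e-3, then moles of
    PCA equivalents at 2 electrons per molecule.  Negative totals (net
    reducing current) are permitted but flagged in the log.
    """
    t = np.asarray(time_h, dtype=float)
    i = np.asarray(current_uA, dtype=float)
    if np.any(np.diff(t) <= 0):
        raise ParameterError("time must be strictly increasing")
    if not np.all(np.isfinite(i)):
        raise ParameterError("current must be finite")
    charge_c = float(np.trapezoid(i, t) * 3.6e-3)
    if charge_c < 0:
        logger.warning("integrate_current: net negative charge (%g C)", charge_c)
    moles = charge_c / (2.0 * 96485.33212)
    return charge_c, moles
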