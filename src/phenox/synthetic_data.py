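"""Synthetic plate-reader and potentiostat data with known ground truth.

Raw assay data for phenazine-oxidation experiments are rarely deposited,
so every downstream stage here (smoothing, metric extraction, replicate
statistics) is exercised against generated data whose true kinetics are
known analytically.

Wells are drawn from a phenomenological curve family emulating 48-hour
fluorescence-decay assays: a lag phase, a weighted two-exponential
(biphasic) decay to a residual floor, an optional initial transient rise
(cells net-reducing the provided PCA before oxidation takes over), and an
abiotic control that drifts slowly rather than staying exactly flat.
Alternatively a well can be backed by a mechanistic
:class:`~phenox.etc_model.EtcModel` trajectory.  Replicate structure
follows the plate design of the assays being emulated: biological
replicates draw jittered parameters around the strain's ground truth;
technical replicates share the biological draw and differ only in
measurement noise.

Fluorescence is linear in reduced-PCA concentration; the calibration
factor is configurable and defaults to 1 AU per uM.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from . import etc_model
from .thermo import FARADAY


class ValidationError(ValueError):
    """Invalid generator parameters; message lists offending fields."""


def default_t_grid(hours: float = 48.0, cadence_h: float = 0.25) -> np.ndarray:
    """Plate-reader grid: every 15 min for 48 h by default (193 points)."""
    return np.arange(0.0, hours + 1e-9, cadence_h)


@dataclass(frozen=True)
class CurveParams:
    """Noiseless fluorescence-decay curve family.

    shape(t) = w exp(-k_fast s) + (1-w) exp(-k_slow s) with s the
    effective post-lag time (a softplus ramp of width
    ``lag_transition_h``; 0 gives a hard kink at the lag).  The curve is
    ``F0 (floor + (1-floor) shape)`` plus an optional transient rise
    peaking at ``rise_tau_h`` with amplitude ``rise_amp * F0``.
    """

    f0: float = 1000.0
    lag_h: float = 3.0
    lag_transition_h: float = 1.0
    k_fast: float = 0.25
    k_slow: float = 0.05
    fast_weight: float = 0.7
    floor_frac: float = 0.05
    rise_amp: float = 0.0
    rise_tau_h: float = 2.0

    def __post_init__(self):
        bad = []
        if self.f0 <= 0:
            bad.append("f0 must be > 0")
        if self.lag_h < 0:
            bad.append("lag_h must be >= 0")
        if self.lag_transition_h < 0:
            bad.append("lag_transition_h must be >= 0")
        if self.k_fast < 0 or self.k_slow < 0:
            bad.append("rate constants must be >= 0")
        if not 0.0 <= self.fast_weight <= 1.0:
            bad.append("fast_weight must be in [0, 1]")
        if not 0.0 <= self.floor_frac < 1.0:
            bad.append("floor_frac must be in [0, 1)")
        if self.rise_amp < 0 or self.rise_tau_h <= 0:
            bad.append("rise_amp must be >= 0 and rise_tau_h > 0")
        if bad:
            raise ValidationError("; ".join(bad))

    # -- analytic curve ------------------------------------------------
    def _s(self, t: np.ndarray) -> np.ndarray:
        """Effective decay time after the lag."""
        if self.lag_transition_h == 0:
            return np.clip(t - self.lag_h, 0.0, None)
        x = (t - self.lag_h) / self.lag_transition_h
        return self.lag_transition_h * np.logaddexp(0.0, x)

    def _ds_dt(self, t: np.ndarray) -> np.ndarray:
        if self.lag_transition_h == 0:
            return (t >= self.lag_h).astype(float)
        x = (t - self.lag_h) / self.lag_transition_h
        return 1.0 / (1.0 + np.exp(-x))

    def shape(self, t: np.ndarray) -> np.ndarray:
        s = self._s(np.asarray(t, dtype=float))
        return (self.fast_weight * np.exp(-self.k_fast * s)
                + (1.0 - self.fast_weight) * np.exp(-self.k_slow * s))

    def expectation(self, t: np.ndarray) -> np.ndarray:
        """Noiseless fluorescence at times t (hours)."""
        t = np.asarray(t, dtype=float)
        base = self.f0 * (self.floor_frac + (1.0 - self.floor_frac) * self.shape(t))
        if self.rise_amp > 0:
            base = base + self.rise_amp * self.f0 * (t / self.rise_tau_h) * np.exp(
                1.0 - t / self.rise_tau_h
            )
        return base

    def derivative(self, t: np.ndarray) -> np.ndarray:
        """Analytic dF/dt."""
        t = np.asarray(t, dtype=float)
        s = self._s(t)
        dshape = -(self.fast_weight * self.k_fast * np.exp(-self.k_fast * s)
                   + (1.0 - self.fast_weight) * self.k_slow * np.exp(-self.k_slow * s))
        out = self.f0 * (1.0 - self.floor_frac) * dshape * self._ds_dt(t)
        if self.rise_amp > 0:
            out = out + self.rise_amp * self.f0 / self.rise_tau_h * np.exp(
                1.0 - t / self.rise_tau_h
            ) * (1.0 - t / self.rise_tau_h)
        return out

    # -- ground-truth metrics ------------------------------------------
    def true_metrics(
        self, horizon_h: float = 48.0, threshold: float = 0.5
    ) -> dict[str, float | bool]:
        """Analytic max oxidation rate, its time, and the threshold
        crossing, on a dense grid of the closed-form derivative."""
        t = np.linspace(0.0, horizon_h, 20001)
        rate = -self.derivative(t)
        i = int(np.argmax(rate))
        baseline = float(self.expectation(np.array([0.0]))[0])
        frac_ox = 1.0 - self.expectation(t) / baseline
        above = frac_ox >= threshold
        if above.any():
            j = int(np.argmax(above))
            if j == 0:
                t_half, detected = 0.0, True
            else:
                f0_, f1 = frac_ox[j - 1], frac_ox[j]
                t_half = float(t[j - 1] + (threshold - f0_) / (f1 - f0_) * (t[j] - t[j - 1]))
                detected = True
        else:
            t_half, detected = np.nan, False
        return {"max_rate": float(rate[i]), "t_at_max": float(t[i]),
                "t_half": t_half, "t_half_detected": detected}


def default_abiotic_params(f0: float = 1000.0) -> CurveParams:
    """Abiotic control: slow roughly linear drift, no lag, no floor."""
    return CurveParams(f0=f0, lag_h=0.0, lag_transition_h=0.0, k_fast=0.002,
                       k_slow=0.0, fast_weight=1.0, floor_frac=0.0)


@dataclass(frozen=True)
class NoiseModel:
    """Per-timepoint measurement noise: multiplicative CV plus additive
    Gaussian, clipped at zero fluorescence."""

    cv: float = 0.005
    sd: float = 1.0
    seed: int | None = None

    def __post_init__(self):
        if self.cv < 0 or self.sd < 0:
            raise ValidationError("noise cv and sd must be >= 0")

    def apply(self, values: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        noisy = values * (1.0 + self.cv * rng.standard_normal(values.shape))
        noisy = noisy + self.sd * rng.standard_normal(values.shape)
        return np.clip(noisy, 0.0, None)


def generate_curve(
    params: CurveParams,
    t_grid: np.ndarray,
    noise: NoiseModel | None = None,
) -> np.ndarray:
    """One well's (possibly noisy) fluorescence series; reproducible for a
    fixed ``noise.seed``."""
    values = params.expectation(np.asarray(t_grid, dtype=float))
    if noise is None or (noise.cv == 0 and noise.sd == 0):
        return values
    rng = np.random.default_rng(noise.seed)
    return noise.apply(values, rng)


@dataclass(frozen=True)
class PlateEntry:
    """One strain's slot in a plate design."""

    strain: str
    source: CurveParams | etc_model.EtcModel
    n_bio: int = 3
    n_tech: int = 3
    kind: str = "sample"  # "sample" or "abiotic"


def _jitter_params(p: CurveParams, spread: float, rng: np.random.Generator) -> CurveParams:
    if spread == 0:
        return p
    g = lambda: float(np.exp(spread * rng.standard_normal()))
    return replace(
        p,
        f0=p.f0 * g(),
        k_fast=p.k_fast * g(),
        k_slow=p.k_slow * g(),
        lag_h=max(0.0, p.lag_h + spread * 5.0 * rng.standard_normal()),
    )


def _model_truth(
    model: etc_model.EtcModel, horizon_h: float, threshold: float,
    calibration: float,
) -> tuple[np.ndarray, dict]:
    """Noiseless model-backed curve on a fine grid plus numeric truth."""
    fine = np.arange(0.0, horizon_h + 1e-9, 0.02)
    traj = etc_model.simulate(model, fine)
    f = traj.pca_red * calibration
    rate = -np.gradient(f, fine)
    i = int(np.argmax(rate))
    baseline = f[0]
    frac_ox = 1.0 - f / baseline if baseline > 0 else np.zeros_like(f)
    above = frac_ox >= threshold
    if above.any():
        j = int(np.argmax(above))
        t_half = float(np.interp(threshold, frac_ox[max(j - 1, 0):j + 1],
                                 fine[max(j - 1, 0):j + 1]))
        detected = True
    else:
        t_half, detected = np.nan, False
    truth = {"max_rate": float(rate[i]), "t_at_max": float(fine[i]),
             "t_half": t_half, "t_half_detected": detected}
    return fine, {"trajectory_f": f, "fine_t": fine, **truth}


def generate_plate(
    design: Sequence[PlateEntry],
    t_grid: np.ndarray | None = None,
    noise: NoiseModel | None = None,
    seed: int | None = None,
    bio_jitter: float = 0.05,
    threshold: float = 0.5,
    calibration: float = 1.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a tidy plate table plus its ground-truth table.

    Biological replicates jitter the strain parameters (relative spread
    ``bio_jitter``); technical replicates share the biological draw and
    differ only in noise.  The truth table records the analytic maximum
    oxidation rate and threshold-crossing time of each noiseless
    biological-replicate curve.
    """
    if t_grid is None:
        t_grid = default_t_grid()
    t_grid = np.asarray(t_grid, dtype=float)
    if noise is None:
        noise = NoiseModel()
    labels = [e.strain for e in design]
    if len(set(labels)) != len(labels):
        raise ValidationError("duplicate strain labels in design")
    rng = np.random.default_rng(seed)

    rows, truth_rows = [], []
    well_counter = 0
    for entry in design:
        for b in range(1, entry.n_bio + 1):
            if isinstance(entry.source, CurveParams):
                drawn = _jitter_params(entry.source, bio_jitter, rng)
                expect = drawn.expectation(t_grid)
                truth = drawn.true_metrics(horizon_h=float(t_grid[-1]),
                                           threshold=threshold)
            else:
                factor = (float(np.exp(bio_jitter * rng.standard_normal()))
                          if bio_jitter > 0 else 1.0)
                p = entry.source.params
                scaled = replace(
                    p,
                    vmax={k: v * factor for k, v in p.vmax.items()},
                    k1={k: v * factor for k, v in p.k1.items()},
                )
                model = etc_model.EtcModel(entry.source.genotype, scaled,
                                           entry.source.condition,
                                           entry.source.acceptor,
                                           entry.source.compat)
                _, info = _model_truth(model, float(t_grid[-1]), threshold,
                                       calibration)
                expect = np.interp(t_grid, info["fine_t"], info["trajectory_f"])
                truth = {k: info[k] for k in
                         ("max_rate", "t_at_max", "t_half", "t_half_detected")}
            truth_rows.append({"strain": entry.strain, "bio_replicate": f"b{b}",
                               **truth})
            for tch in range(1, entry.n_tech + 1):
                well_counter += 1
                well = f"W{well_counter:02d}"
                values = noise.apply(expect, rng) if (noise.cv or noise.sd) else expect
                rtype = ("abiotic" if entry.kind == "abiotic"
                         else ("technical" if entry.n_tech > 1 else "biological"))
                rows.append(pd.DataFrame({
                    "time_h": t_grid,
                    "well": well,
                    "strain": entry.strain,
                    "replicate_id": f"b{b}-t{tch}",
                    "replicate_type": rtype,
                    "fluorescence": values,
                }))
    plate = pd.concat(rows, ignore_index=True)
    return plate, pd.DataFrame(truth_rows)


def generate_current_trace(
    model: etc_model.EtcModel,
    t_grid: np.ndarray | None = None,
    spikes: Sequence[tuple[float, float]] = (),
    noise: NoiseModel | None = None,
    volume_L: float = 0.01,
    clamp_pca_red: bool = True,
) -> pd.DataFrame:
    """Chronoamperometry trace from a model trajectory.

    With the working electrode poised to keep PCA reduced
    (``clamp_pca_red``), current is proportional to the instantaneous PCA
    oxidation flux (2 electrons per PCA): it decays to zero as the
    acceptor exhausts and resumes at each spike.
    """
    if t_grid is None:
        t_grid = default_t_grid()
    if any(spikes[i][0] > spikes[i + 1][0] for i in range(len(spikes) - 1)):
        raise ValidationError("spikes must be sorted by time")
    traj = etc_model.simulate(model, np.asarray(t_grid, dtype=float),
                              spikes=spikes, clamp_pca_red=clamp_pca_red)
    flux = traj.oxidation_flux()  # uM / h
    current_uA = 2.0 * FARADAY * flux * 1e-6 * volume_L / 3600.0 * 1e6
    if noise is not None and (noise.cv or noise.sd):
        rng = np.random.default_rng(noise.seed)
        current_uA = current_uA * (1.0 + noise.cv * rng.standard_normal(current_uA.shape)) \
            + noise.sd * rng.standard_normal(current_uA.shape)
    return pd.DataFrame({"time_h": np.asarray(t_grid, dtype=float),
                         "current_uA": current_uA})
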