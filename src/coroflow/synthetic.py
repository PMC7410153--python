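"""Synthetic bench data with known ground truth.

Real chamber-characterization sweeps are laboratory measurements; this module
emulates them so every estimator and solver in the package is testable end to
end.  It generates constant-flow sweep measurements (ΔP = R·Q plus a chosen
noise model on the pressure channel), programmable-pump inflow waveforms, and
a Monte-Carlo recovery harness reporting estimator bias and spread.

Noise is applied to pressure only: a calibrated programmable pump delivers
its setpoint flow far more precisely than a bench pressure sensor reads ΔP.
All randomness flows from one explicit seed — regenerating from a recorded
provenance triple (truth, noise, seed) reproduces the measurements exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .chamber import (
    DEFAULT_SWEEP_ML_MIN,
    FlowMeasurement,
    characterize,
    sweep_protocol,
    write_measurements,
)
from .presets import MEASURED_CHAMBER_RESISTANCE, Vessel
from .units import ml_min_to_cm3_s

__all__ = [
    "NoiseModel",
    "SyntheticExperiment",
    "Waveform",
    "generate_chamber_experiment",
    "generate_pump_waveform",
    "recovery_suite",
]

_NOISE_KINDS = ("none", "gaussian_relative", "gaussian_absolute")

#: default relative pressure noise — exercises the estimators without
#: swamping them (bench pressure sensors are typically ~1–2% devices)
DEFAULT_NOISE_SIGMA = 0.02


@dataclass(frozen=True)
class NoiseModel:
    """Measurement-noise description for the pressure channel.

    ``gaussian_relative``: ΔP ← ΔP·(1 + σ·ε); ``gaussian_absolute``:
    ΔP ← ΔP + σ·ε with σ in dyn/cm²; ε ~ N(0, 1).  Negative perturbed
    pressures are clipped to zero (a gauge cannot report reverse drop in a
    constant-flow sweep).
    """

    kind: str = "none"
    sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in _NOISE_KINDS:
            raise ValueError(f"unknown noise kind {self.kind!r}; expected {_NOISE_KINDS}")
        if self.sigma < 0:
            raise ValueError(f"sigma must be >= 0, got {self.sigma}")

    def apply(self, dp: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        if self.kind == "none" or self.sigma == 0.0:
            return np.asarray(dp, dtype=float).copy()
        eps = rng.standard_normal(len(dp))
        if self.kind == "gaussian_relative":
            out = dp * (1.0 + self.sigma * eps)
        else:
            out = dp + self.sigma * eps
        return np.clip(out, 0.0, None)


@dataclass(frozen=True)
class SyntheticExperiment:
    """A generated sweep with its full provenance (truth, noise, seed)."""

    true_resistance: Mapping[Vessel, float]
    sweep_ml_min: tuple[float, ...]
    measurements: Mapping[Vessel, tuple[FlowMeasurement, ...]]
    noise: NoiseModel

    @property
    def provenance(self) -> dict:
        return {
            "true_resistance": {v.value: r for v, r in self.true_resistance.items()},
            "sweep_ml_min": list(self.sweep_ml_min),
            "noise": {"kind": self.noise.kind, "sigma": self.noise.sigma,
                      "seed": self.noise.seed},
        }

    def write(self, path: str | Path, pressure_unit: str = "dynes_cm2") -> Path:
        """Write measurements as delimited text plus a JSON provenance sidecar."""
        path = Path(path)
        all_meas = [m for ms in self.measurements.values() for m in ms]
        write_measurements(all_meas, path, pressure_unit=pressure_unit)
        sidecar = path.with_suffix(path.suffix + ".provenance.json")
        sidecar.write_text(json.dumps(self.provenance, indent=2, sort_keys=True))
        return path


def generate_chamber_experiment(
    truth: Mapping[Vessel | str, float] | None = None,
    sweep_ml_min: Sequence[float] | None = None,
    noise: NoiseModel | None = None,
) -> SyntheticExperiment:
    """Emulate the stand-alone chamber flow experiment.

    Constant flow is driven through each chamber separately over the sweep
    setpoints (default 80–160 mL/min in 20 mL/min steps); the true pressure
    drop R·Q is perturbed by the noise model.  Deterministic under a fixed
    seed.  Default truths are the shipped measured chamber resistances.
    """
    if truth is None:
        truth = dict(MEASURED_CHAMBER_RESISTANCE)
    truth = {Vessel(v): float(r) for v, r in truth.items()}
    for v, r in truth.items():
        if not r > 0:
            raise ValueError(f"true resistance must be > 0, got {r} for {v.value}")
    if sweep_ml_min is None:
        sweep_ml_min = sweep_protocol(*DEFAULT_SWEEP_ML_MIN)
    sweep_ml_min = tuple(float(q) for q in sweep_ml_min)
    if not sweep_ml_min:
        raise ValueError("sweep must contain at least one setpoint")
    noise = noise or NoiseModel()

    rng = np.random.default_rng(noise.seed)
    flows = np.array([ml_min_to_cm3_s(q) for q in sweep_ml_min])
    measurements: dict[Vessel, tuple[FlowMeasurement, ...]] = {}
    for vessel in sorted(truth, key=lambda v: v.value):  # stable draw order
        dp_true = truth[vessel] * flows
        dp = noise.apply(dp_true, rng)
        measurements[vessel] = tuple(
            FlowMeasurement(q, p, vessel) for q, p in zip(flows, dp)
        )
    return SyntheticExperiment(
        true_resistance=truth,
        sweep_ml_min=sweep_ml_min,
        measurements=measurements,
        noise=noise,
    )


# ---------------------------------------------------------------------------
# pump waveforms


@dataclass(frozen=True)
class Waveform:
    """A sampled inflow waveform, callable at arbitrary times (linear interp)."""

    times: np.ndarray
    values: np.ndarray

    def __call__(self, t: float) -> float:
        return float(np.interp(t, self.times, self.values))

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        pd.DataFrame({"time_s": self.times, "flow_cm3_s": self.values}).to_csv(
            path, index=False
        )
        return path

    @classmethod
    def read(cls, path: str | Path) -> "Waveform":
        df = pd.read_csv(path)
        for col in ("time_s", "flow_cm3_s"):
            if col not in df.columns:
                raise ValueError(f"{path}: missing column {col!r}")
        return cls(df["time_s"].to_numpy(float), df["flow_cm3_s"].to_numpy(float))


def generate_pump_waveform(
    kind: str,
    params: Mapping[str, object] | None = None,
    duration: float = 10.0,
    dt: float = 0.01,
) -> Waveform:
    """Build a programmable-pump inflow waveform.

    Kinds: ``constant`` (params: ``flow_cm3_s``), ``sinusoid`` (params:
    ``mean``, ``amplitude``, ``frequency_hz``, optional ``phase``), ``table``
    (params: ``path`` to a ``time_s,flow_cm3_s`` CSV, linearly interpolated
    and resampled on the requested grid).
    """
    if not duration > 0:
        raise ValueError(f"duration must be > 0, got {duration}")
    if not dt > 0:
        raise ValueError(f"dt must be > 0, got {dt}")
    params = dict(params or {})
    t = dt * np.arange(int(round(duration / dt)) + 1)
    if kind == "constant":
        q0 = float(params.get("flow_cm3_s", 1.33))
        values = np.full_like(t, q0)
    elif kind == "sinusoid":
        mean = float(params.get("mean", 1.33))
        amp = float(params.get("amplitude", 0.5))
        f_hz = float(params.get("frequency_hz", 1.0))
        phase = float(params.get("phase", 0.0))
        values = mean + amp * np.sin(2 * np.pi * f_hz * t + phase)
    elif kind == "table":
        source = Waveform.read(params["path"])
        values = np.interp(t, source.times, source.values)
    else:
        raise ValueError(
            f"unknown waveform kind {kind!r}; expected constant, sinusoid or table"
        )
    return Waveform(times=t, values=values)


# ---------------------------------------------------------------------------
# estimator validation harness


def recovery_suite(
    truth: float = 1671.0,
    noise_levels: Sequence[float] = (0.0, 0.02, 0.04),
    replicates: int = 1000,
    seed: int = 0,
    sweep_ml_min: Sequence[float] | None = None,
) -> pd.DataFrame:
    """Monte-Carlo recovery report for the sweep resistance estimators.

    For each relative-noise level, generates ``replicates`` independent
    sweeps at the given true resistance, characterizes each, and reports the
    mean estimate, bias, and SD across replicates for both the mean-of-ratios
    and through-origin-slope estimators.  Deterministic under a fixed seed.
    """
    if replicates < 1:
        raise ValueError(f"replicates must be >= 1, got {replicates}")
    if not truth > 0:
        raise ValueError(f"truth must be > 0, got {truth}")
    if sweep_ml_min is None:
        sweep_ml_min = sweep_protocol(*DEFAULT_SWEEP_ML_MIN)
    flows = np.array([ml_min_to_cm3_s(q) for q in sweep_ml_min])
    root = np.random.default_rng(seed)

    rows = []
    for sigma in noise_levels:
        noise = NoiseModel("gaussian_relative" if sigma > 0 else "none", sigma, seed)
        rng = np.random.default_rng(root.integers(2**31))
        mean_est = np.empty(replicates)
        slope_est = np.empty(replicates)
        for i in range(replicates):
            dp = noise.apply(truth * flows, rng)
            meas = [FlowMeasurement(q, p) for q, p in zip(flows, dp)]
            result = characterize(meas)
            mean_est[i] = result.mean_resistance
            slope_est[i] = result.slope_resistance
        for name, est in (("mean", mean_est), ("slope", slope_est)):
            rows.append(
                {
                    "estimator": name,
                    "sigma": sigma,
                    "truth": truth,
                    "mean_estimate": float(est.mean()),
                    "bias": float(est.mean() - truth),
                    "sd": float(est.std(ddof=1)) if replicates > 1 else 0.0,
                    "replicates": replicates,
                }
            )
    return pd.DataFrame(rows)
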