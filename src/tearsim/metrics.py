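"""Goodness-of-fit metrics for predicted vs observed tear concentrations.

Model validation compares the simulated tear-film averaged concentration
profile against sparse clinical sampling (typically 0.25, 0.5, 1, 2, 4, 6
and 24 h post-dose) using the coefficient of determination R², the root
mean squared error RMSE (concentration units), and the average absolute
relative deviation AARD (percent).  An explicit time window restricts the
comparison (e.g. to the first six hours, where late samples are near the
assay floor).

Clinical series are supplied by the user as CSV (columns ``time_h``,
``conc_ug_per_mL``, optional ``sd``); a synthetic fixture generator
(plateau at the solubility limit followed by exponential decay, lognormal
noise) exercises this path without external data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ObservedSeries",
    "r_squared",
    "rmse",
    "aard",
    "synthetic_observed_series",
]

STANDARD_SAMPLING_HOURS = (0.25, 0.5, 1.0, 2.0, 4.0, 6.0, 24.0)


@dataclass(frozen=True)
class ObservedSeries:
    """Observed concentration-time series (times [h], conc [µg/mL])."""

    times_h: tuple[float, ...]
    concentrations: tuple[float, ...]
    sds: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times_h)
        c = np.asarray(self.concentrations)
        if len(t) != len(c):
            raise ValueError("times and concentrations must align")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(c < 0):
            raise ValueError("concentrations must be non-negative")
        if self.sds is not None and len(self.sds) != len(t):
            raise ValueError("sds must align with times")

    @classmethod
    def from_csv(cls, path) -> "ObservedSeries":
        df = pd.read_csv(path)
        sds = tuple(df["sd"]) if "sd" in df.columns else None
        return cls(
            times_h=tuple(df["time_h"]),
            concentrations=tuple(df["conc_ug_per_mL"]),
            sds=sds,
        )

    def to_csv(self, path) -> None:
        cols = {"time_h": self.times_h, "conc_ug_per_mL": self.concentrations}
        if self.sds is not None:
            cols["sd"] = self.sds
        pd.DataFrame(cols).to_csv(path, index=False)

    def window(self, t_max_h: float) -> "ObservedSeries":
        keep = [i for i, t in enumerate(self.times_h) if t <= t_max_h]
        return ObservedSeries(
            times_h=tuple(self.times_h[i] for i in keep),
            concentrations=tuple(self.concentrations[i] for i in keep),
            sds=tuple(self.sds[i] for i in keep) if self.sds else None,
        )


def _paired(observed, predicted, min_len: int) -> tuple[np.ndarray, np.ndarray]:
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape:
        raise ValueError("observed and predicted must have equal length")
    if obs.size < min_len:
        raise ValueError(f"need at least {min_len} paired values")
    return obs, pred


def r_squared(observed, predicted) -> float:
    """Coefficient of determination, 1 − SS_res/SS_tot."""
    obs, pred = _paired(observed, predicted, 2)
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("observed series has zero variance")
    return 1.0 - float(np.sum((obs - pred) ** 2)) / ss_tot


def rmse(observed, predicted) -> float:
    """Root mean squared error in the observations' units."""
    obs, pred = _paired(observed, predicted, 1)
    return float(np.sqrt(np.mean((obs - pred) ** 2)))


def aard(observed, predicted) -> float:
    """Average absolute relative deviation, percent."""
    obs, pred = _paired(observed, predicted, 1)
    if np.any(obs == 0):
        raise ValueError("AARD undefined for zero observations")
    return 100.0 * float(np.mean(np.abs(pred - obs) / np.abs(obs)))


def synthetic_observed_series(
    seed: int,
    times_h=STANDARD_SAMPLING_HOURS,
    plateau: float = 100.0,
    t_plateau_h: float = 1.0,
    half_life_h: float = 1.0,
    noise_cv: float = 0.25,
) -> ObservedSeries:
    """SYNTHETIC stand-in for a clinical tear-concentration series.

    Plateau at the solubility limit while particles persist, then
    first-order decay, perturbed by lognormal sampling noise.  This mimics
    only the shape of the clinical profile (not its between-subject
    variability structure) and exists so the metrics path is fully testable
    without external data.
    """
    rng = np.random.default_rng(seed)
    t = np.asarray(times_h, dtype=float)
    clean = np.where(
        t <= t_plateau_h,
        plateau,
        plateau * np.exp(-np.log(2.0) * (t - t_plateau_h) / half_life_h),
    )
    sigma = np.sqrt(np.log(1.0 + noise_cv**2))
    noisy = clean * rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=t.size)
    noisy = np.maximum(noisy, 1e-6)
    return ObservedSeries(
        times_h=tuple(t),
        concentrations=tuple(noisy),
        sds=tuple(noise_cv * clean),
    )
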