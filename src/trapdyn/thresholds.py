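"""Interaction sign-change thresholds and population-growth regions.

With a fitted linear predictor β_ar·a + β_T·T + β_H·H + β_int·T·H, the
partial effect of temperature is β_T + β_int·H, which changes sign at the
humidity H* = −β_T/β_int; symmetrically the humidity effect flips at
T* = −β_H/β_int.  Above both thresholds warmer-and-more-humid weeks raise
expected abundance, below both they lower it.

The growth condition asks whether next week's predicted per-trap abundance
exceeds this week's: exp(β_ar·a + β_T·T + β_H·H + β_int·T·H) > a.  The
trap-effort offset cancels in this per-trap comparison.  Scenario
abundances follow the study's low/median/high per-trap values
(0.111, 0.56, 0.99 mosquitoes per week per trap).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .glm import NBFit

__all__ = [
    "SCENARIO_ABUNDANCES",
    "ThresholdPair",
    "GrowthMap",
    "sign_change_thresholds",
    "growth_condition",
    "growth_map",
]

#: low / middle / high previous-week per-trap abundance scenarios
SCENARIO_ABUNDANCES = {"low": 0.111, "middle": 0.56, "high": 0.99}

DEFAULT_T_RANGE = (10.0, 32.0)
DEFAULT_H_RANGE = (30.0, 100.0)


class UndefinedThresholdError(ValueError):
    """Raised when the interaction coefficient is zero (no sign change)."""


def _roles(fit_or_coefs) -> dict[str, float]:
    if isinstance(fit_or_coefs, NBFit):
        coefs = fit_or_coefs.coef_by_role()
    else:
        coefs = dict(fit_or_coefs)
    missing = {"temperature", "humidity", "interaction"} - coefs.keys()
    if missing:
        raise ValueError(f"fit lacks required coefficients: {sorted(missing)}")
    coefs.setdefault("ar", 0.0)
    return coefs


@dataclass(frozen=True)
class ThresholdPair:
    """Sign-change thresholds: h_star in %, t_star in °C."""

    h_star: float
    t_star: float

    def rounded(self, ndigits: int = 1) -> "ThresholdPair":
        return ThresholdPair(round(self.h_star, ndigits), round(self.t_star, ndigits))


def sign_change_thresholds(fit) -> ThresholdPair:
    """Humidity and temperature values where the partner effect flips sign.

    ``fit`` is an :class:`~trapdyn.glm.NBFit` with temperature, humidity and
    interaction coefficients, or a mapping with those keys.
    """
    c = _roles(fit)
    if c["interaction"] == 0:
        raise UndefinedThresholdError(
            "sign-change thresholds undefined: interaction coefficient is zero"
        )
    return ThresholdPair(
        h_star=-c["temperature"] / c["interaction"],
        t_star=-c["humidity"] / c["interaction"],
    )


def growth_condition(fit, y_prev: float, temperature, humidity):
    """Whether the model predicts per-trap population growth at (T, H).

    True iff exp(β_ar·y_prev + β_T·T + β_H·H + β_int·T·H) > y_prev.
    Vectorized over temperature/humidity arrays.
    """
    if y_prev <= 0:
        raise ValueError("y_prev must be > 0")
    c = _roles(fit)
    T = np.asarray(temperature, dtype=float)
    H = np.asarray(humidity, dtype=float)
    eta = (c["ar"] * y_prev + c["temperature"] * T
           + c["humidity"] * H + c["interaction"] * T * H)
    return np.exp(eta) > y_prev


@dataclass(frozen=True)
class GrowthMap:
    """Boolean growth region over a (temperature, humidity) grid.

    ``growth[i, j]`` refers to temperature ``t_grid[i]`` and humidity
    ``h_grid[j]``.  ``frontier`` is, per temperature, the least humidity at
    which growth is predicted (NaN where no grid humidity suffices).
    """

    t_grid: np.ndarray
    h_grid: np.ndarray
    growth: np.ndarray
    y_prev: float
    frontier: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.growth.astype(int), index=self.t_grid,
                          columns=self.h_grid)
        df.index.name = "temperature_c"
        df.columns.name = "humidity_pct"
        return df

    def sidecar(self, thresholds: ThresholdPair | None = None) -> dict:
        meta = {
            "y_prev": self.y_prev,
            "t_range": [float(self.t_grid[0]), float(self.t_grid[-1])],
            "h_range": [float(self.h_grid[0]), float(self.h_grid[-1])],
            "growth_fraction": float(self.growth.mean()),
            "frontier": {
                f"{t:.1f}": (None if np.isnan(f) else round(float(f), 1))
                for t, f in zip(self.t_grid, self.frontier)
            },
        }
        if thresholds is not None:
            r = thresholds.rounded()
            meta["h_star_pct"] = r.h_star
            meta["t_star_c"] = r.t_star
        return meta


def growth_map(fit, y_prev: float,
               t_range: tuple[float, float] = DEFAULT_T_RANGE,
               h_range: tuple[float, float] = DEFAULT_H_RANGE,
               t_step: float = 0.1, h_step: float = 0.5) -> GrowthMap:
    """Evaluate :func:`growth_condition` on a regular (T, H) grid."""
    if t_range[1] < t_range[0] or h_range[1] < h_range[0]:
        raise ValueError("ranges must be (low, high)")
    t_grid = np.arange(t_range[0], t_range[1] + 0.5 * t_step, t_step)
    h_grid = np.arange(h_range[0], h_range[1] + 0.5 * h_step, h_step)
    TT, HH = np.meshgrid(t_grid, h_grid, indexing="ij")
    growth = growth_condition(fit, y_prev, TT, HH)
    frontier = np.full(len(t_grid), np.nan)
    for i in range(len(t_grid)):
        j = np.argmax(growth[i])
        if growth[i, j]:
            frontier[i] = h_grid[j]
    return GrowthMap(t_grid=t_grid, h_grid=h_grid, growth=growth,
                     y_prev=float(y_prev), frontier=frontier)


def write_growth_map(gmap: GrowthMap, csv_path, json_path=None,
                     thresholds: ThresholdPair | None = None) -> None:
    gmap.to_frame().to_csv(csv_path)
    if json_path is not None:
        with open(json_path, "w") as fh:
            json.dump(gmap.sidecar(thresholds), fh, indent=2)
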