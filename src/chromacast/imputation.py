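"""Stochastic regression imputation of missing per-minute sensor values.

A trend + harmonic regression (intercept, linear drift, sin/cos pairs at
the diurnal and half-diurnal periods) is fit by ordinary least squares on
the observed cells only.  Missing cells are filled with the fitted value
plus a Gaussian draw scaled by the residual standard deviation, so the
imputed series preserves both the seasonal structure and the noise level
of the observed data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .rems_io import Parameter, SensorSeries

__all__ = [
    "DEFAULT_PERIODS",
    "CLIP_BOUNDS",
    "ImputationModel",
    "fit_stochastic_model",
    "impute",
]

#: Harmonic periods, minutes (diurnal and half-diurnal).
DEFAULT_PERIODS: tuple[float, ...] = (1440.0, 720.0)

#: Physical clipping bounds applied to imputed draws, per parameter.
CLIP_BOUNDS: dict[Parameter, tuple[float, float]] = {
    Parameter.TEMPERATURE: (-40.0, 60.0),
    Parameter.HUMIDITY: (0.0, 100.0),
    Parameter.LIGHT: (0.0, np.inf),
    Parameter.SOIL_MOISTURE: (0.0, np.inf),
    Parameter.SOIL_PH: (0.0, 14.0),
}

#: Fraction of missing cells above which a warning (not an error) is raised.
LONG_GAP_WARN_FRACTION = 0.5


@dataclass
class ImputationModel:
    """Fitted trend + harmonic regression for one sensor channel."""

    parameter: Parameter
    coeffs: np.ndarray          # [intercept, slope, (sin, cos) per period]
    periods: tuple[float, ...]  # periods with harmonic terms retained
    residual_sd: float
    fit_window: int             # minutes spanned by the fit

    def __post_init__(self) -> None:
        self.coeffs = np.asarray(self.coeffs, dtype=float)
        if self.residual_sd < 0:
            raise ValueError("residual_sd must be >= 0")

    def design(self, t: np.ndarray) -> np.ndarray:
        cols = [np.ones_like(t, dtype=float), t / 1440.0]
        for period in self.periods:
            w = 2.0 * np.pi * t / period
            cols.append(np.sin(w))
            cols.append(np.cos(w))
        return np.column_stack(cols)

    def fitted(self, t: np.ndarray) -> np.ndarray:
        """Deterministic regression prediction at minutes ``t``."""
        return self.design(np.asarray(t, dtype=float)) @ self.coeffs

    def harmonic_amplitude(self, period: float) -> float:
        """Amplitude of the fitted harmonic at ``period`` minutes."""
        i = self.periods.index(period)
        a, b = self.coeffs[2 + 2 * i], self.coeffs[3 + 2 * i]
        return float(np.hypot(a, b))


def fit_stochastic_model(
    s: SensorSeries, periods: tuple[float, ...] = DEFAULT_PERIODS
) -> ImputationModel:
    """Least-squares fit of trend + harmonics on the observed cells.

    Harmonic terms for a period are dropped when the observed span covers
    fewer than two full cycles of that period.  Requires at least 10% of
    cells observed.
    """
    if not s.regular:
        raise ValueError("fit requires a regularized (per-minute) series")
    obs = ~s.missing_mask
    n_obs = int(obs.sum())
    if n_obs < max(4, int(0.10 * s.n_points)):
        raise ValueError(
            f"too few observations to fit: {n_obs}/{s.n_points} observed"
        )
    t_obs = s.timestamps[obs]
    span = float(t_obs[-1] - t_obs[0])
    kept = tuple(p for p in periods if span >= 2.0 * p)
    model = ImputationModel(
        parameter=s.parameter,
        coeffs=np.zeros(2 + 2 * len(kept)),
        periods=kept,
        residual_sd=0.0,
        fit_window=int(round(span)),
    )
    design = model.design(t_obs)
    coeffs, *_ = np.linalg.lstsq(design, s.observed_values(), rcond=None)
    resid = s.observed_values() - design @ coeffs
    model.coeffs = coeffs
    model.residual_sd = float(np.std(resid))
    return model


def impute(s: SensorSeries, m: ImputationModel, seed: int) -> SensorSeries:
    """Fill missing cells with fitted values plus seeded Gaussian noise.

    Observed cells are never altered.  Imputed draws are clipped to the
    parameter's physical bounds.  The returned series has an empty missing
    mask and a per-cell provenance flag (``imputed_mask``).
    """
    if m.parameter != s.parameter:
        raise ValueError(
            f"model fitted for {m.parameter.value}, series is {s.parameter.value}"
        )
    missing = s.missing_mask
    if missing.mean() > LONG_GAP_WARN_FRACTION:
        warnings.warn(
            f"{s.parameter.value}: {missing.mean():.0%} of cells are missing; "
            "imputation quality may be poor",
            stacklevel=2,
        )
    values = s.values.copy()
    if missing.any():
        rng = np.random.default_rng(seed)
        t_miss = s.timestamps[missing]
        draws = m.fitted(t_miss) + rng.normal(0.0, m.residual_sd, size=t_miss.shape)
        lo, hi = CLIP_BOUNDS[s.parameter]
        values[missing] = np.clip(draws, lo, hi)
    out = SensorSeries(
        parameter=s.parameter,
        timestamps=s.timestamps.copy(),
        values=values,
        missing_mask=np.zeros(s.n_points, dtype=bool),
        start_time=s.start_time,
        regular=s.regular,
        provenance=dict(s.provenance),
    )
    out.provenance["imputed_mask"] = missing.copy()
    return out
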