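"""Normalization, Gramian angular field encoding and tensor assembly.

Imputed per-minute series are mapped into [0, 1] with trailing-window
technical indicators (Williams %R rescaled to [0, 1], stochastic %K and
its %D smoothing), reduced to a 128-vector by piecewise aggregate
approximation, and turned into 128 x 128 Gramian angular summation or
difference field images.  One image per (indicator, k, d) grid combination
augments the training set; five per-parameter images are assembled into a
single CNN input tensor.
"""

from __future__ import annotations

import enum
import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .rems_io import CHANNEL_ORDER, Parameter, SensorSeries

__all__ = [
    "Indicator",
    "IndicatorConfig",
    "NormalizedSeries",
    "FieldKind",
    "GramianImage",
    "Layout",
    "InputTensor",
    "DEFAULT_K_GRID",
    "DEFAULT_D_GRID",
    "IMAGE_SIZE",
    "williams_r",
    "stochastic_oscillator",
    "normalize",
    "paa_resample",
    "gasf",
    "gadf",
    "augment",
    "assemble_input",
]

IMAGE_SIZE = 128
DEFAULT_K_GRID: tuple[int, ...] = (5, 20, 30, 60, 720, 1440, 4320, 7200)
DEFAULT_D_GRID: tuple[int, ...] = (720, 1440, 4320)
_FLAT_EPS = 1e-12


class Indicator(str, enum.Enum):
    WILLIAMS_R = "williams_r"
    STOCHASTIC_K = "stochastic_K"
    STOCHASTIC_D = "stochastic_D"


class FieldKind(str, enum.Enum):
    GASF = "GASF"
    GADF = "GADF"


class Layout(str, enum.Enum):
    CONCAT_1D = "concat_1d"    # 640 x 128 x 1
    STACKED_5D = "stacked_5d"  # 128 x 128 x 5


@dataclass(frozen=True)
class IndicatorConfig:
    """Normalization indicator plus its (k, d) window lengths in minutes."""

    indicator: Indicator
    k: int
    d: int = 1

    def __post_init__(self) -> None:
        if self.k < 1 or self.d < 1:
            raise ValueError("window lengths k and d must be >= 1")


@dataclass
class NormalizedSeries:
    """Per-minute series mapped into [0, 1] by a technical indicator."""

    values: np.ndarray
    parameter: Parameter
    config: IndicatorConfig

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        finite = self.values[np.isfinite(self.values)]
        if finite.size and (finite.min() < -1e-9 or finite.max() > 1 + 1e-9):
            raise ValueError("normalized values must lie in [0, 1]")


@dataclass
class GramianImage:
    """Square Gramian angular field image with its provenance."""

    matrix: np.ndarray
    field_kind: FieldKind
    parameter: Parameter | None = None
    config: IndicatorConfig | None = None

    @property
    def size(self) -> int:
        return self.matrix.shape[0]


@dataclass
class InputTensor:
    """CNN-ready W x H x D array in a fixed channel order."""

    array: np.ndarray
    layout: Layout
    field_kind: FieldKind
    config: IndicatorConfig | None = None


def _rolling_extrema(x: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    ser = pd.Series(x)
    hi = ser.rolling(k, min_periods=1).max().to_numpy()
    lo = ser.rolling(k, min_periods=1).min().to_numpy()
    return hi, lo


def _check_k(n: int, k: int) -> None:
    k_max = -(-n // IMAGE_SIZE)  # ceil(n / 128)
    if k > k_max:
        warnings.warn(
            "indicator window k exceeds the per-pixel upper bound ceil(n/128); "
            "augmented images will share pixels across windows",
            stacklevel=3,
        )


def williams_r(s: SensorSeries, k: int) -> NormalizedSeries:
    """Williams %R over a trailing k-minute window, rescaled to [0, 1].

    value(t) = (max - x_t) / (max - min) over [t-k+1, t]; the window is
    truncated at the series start and flat windows map to 0.5.  Cells that
    are missing in the input stay NaN in the output.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    _check_k(s.n_points, k)
    x = s.values
    hi, lo = _rolling_extrema(x, k)
    rng = hi - lo
    out = np.where(rng > _FLAT_EPS, (hi - x) / np.where(rng > _FLAT_EPS, rng, 1.0), 0.5)
    out[np.isnan(x)] = np.nan
    return NormalizedSeries(out, s.parameter, IndicatorConfig(Indicator.WILLIAMS_R, k))


def stochastic_oscillator(s: SensorSeries, k: int, d: int = 1) -> NormalizedSeries:
    """Stochastic oscillator %D: a d-minute moving average of %K.

    %K(t) = (x_t - min) / (max - min) over the trailing k-minute window;
    with d = 1 this is %K itself.  Flat windows map to 0.5; missing input
    cells stay NaN.
    """
    if k < 1 or d < 1:
        raise ValueError("k and d must be >= 1")
    _check_k(s.n_points, k)
    x = s.values
    hi, lo = _rolling_extrema(x, k)
    rng = hi - lo
    pk = np.where(rng > _FLAT_EPS, (x - lo) / np.where(rng > _FLAT_EPS, rng, 1.0), 0.5)
    pk[np.isnan(x)] = np.nan
    if d > 1:
        pk = pd.Series(pk).rolling(d, min_periods=1).mean().to_numpy()
        pk[np.isnan(x)] = np.nan
        indicator = Indicator.STOCHASTIC_D
    else:
        indicator = Indicator.STOCHASTIC_K
    return NormalizedSeries(pk, s.parameter, IndicatorConfig(indicator, k, d))


def normalize(s: SensorSeries, config: IndicatorConfig) -> NormalizedSeries:
    """Apply the indicator named by ``config`` to a series."""
    if config.indicator is Indicator.WILLIAMS_R:
        return williams_r(s, config.k)
    if config.indicator is Indicator.STOCHASTIC_K:
        return stochastic_oscillator(s, config.k, 1)
    return stochastic_oscillator(s, config.k, config.d)


def paa_resample(ns: NormalizedSeries | np.ndarray, m: int = IMAGE_SIZE) -> np.ndarray:
    """Piecewise aggregate approximation to a length-``m`` vector.

    The n input minutes are split into m near-equal contiguous segments
    (sizes floor(n/m) or ceil(n/m)); each output entry is its segment's
    mean.  NaNs propagate into their segment.
    """
    x = ns.values if isinstance(ns, NormalizedSeries) else np.asarray(ns, dtype=float)
    n = len(x)
    if n < m:
        raise ValueError(f"cannot PAA-resample length {n} to {m} segments")
    if n == m:
        return x.copy()
    bounds = (np.arange(m + 1) * n) // m
    sums = np.add.reduceat(x, bounds[:-1])
    return sums / np.diff(bounds)


def _check_unit_interval(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    if v.ndim != 1:
        raise ValueError("expected a one-dimensional vector")
    finite = v[np.isfinite(v)]
    if finite.size and (finite.min() < -1e-9 or finite.max() > 1 + 1e-9):
        raise ValueError("Gramian encoding requires entries in [0, 1]")
    return np.clip(v, 0.0, 1.0)  # NaN passes through clip unchanged


def gasf(v: np.ndarray, **provenance) -> GramianImage:
    """Gramian angular summation field: GASF[i, j] = cos(phi_i + phi_j).

    phi = arccos(v) with v in [0, 1].  NaN entries (non-imputed mode)
    propagate to their row/column.
    """
    v = _check_unit_interval(v)
    phi = np.arccos(v)
    return GramianImage(np.cos(phi[:, None] + phi[None, :]), FieldKind.GASF, **provenance)


def gadf(v: np.ndarray, **provenance) -> GramianImage:
    """Gramian angular difference field: GADF[i, j] = sin(phi_i - phi_j)."""
    v = _check_unit_interval(v)
    phi = np.arccos(v)
    return GramianImage(np.sin(phi[:, None] - phi[None, :]), FieldKind.GADF, **provenance)


def iter_configs(
    k_grid: tuple[int, ...] = DEFAULT_K_GRID,
    d_grid: tuple[int, ...] = DEFAULT_D_GRID,
    indicators: tuple[Indicator, ...] = tuple(Indicator),
) -> list[IndicatorConfig]:
    """Enumerate the augmentation grid (d applies to stochastic %D only)."""
    configs: list[IndicatorConfig] = []
    for ind in indicators:
        if ind is Indicator.STOCHASTIC_D:
            configs.extend(
                IndicatorConfig(ind, k, d) for k, d in itertools.product(k_grid, d_grid)
            )
        else:
            configs.extend(IndicatorConfig(ind, k) for k in k_grid)
    return configs


def augment(
    s: SensorSeries,
    k_grid: tuple[int, ...] = DEFAULT_K_GRID,
    d_grid: tuple[int, ...] = DEFAULT_D_GRID,
    field_kind: FieldKind = FieldKind.GASF,
    indicators: tuple[Indicator, ...] = tuple(Indicator),
    limit: int | None = None,
    size: int = IMAGE_SIZE,
) -> list[GramianImage]:
    """One Gramian image per retained (indicator, k, d) combination.

    NaN cells surviving normalization (non-imputed mode) are zeroed in the
    image so the CNN sees corrupted pixels rather than NaNs.
    """
    if not k_grid or (Indicator.STOCHASTIC_D in indicators and not d_grid):
        raise ValueError("augmentation grids must be non-empty")
    configs = iter_configs(tuple(k_grid), tuple(d_grid), tuple(indicators))
    if limit is not None:
        configs = configs[:limit]
    images = []
    transform = gasf if field_kind is FieldKind.GASF else gadf
    for cfg in configs:
        v = paa_resample(normalize(s, cfg), size)
        img = transform(v, parameter=s.parameter, config=cfg)
        np.nan_to_num(img.matrix, copy=False)
        images.append(img)
    return images


def assemble_input(images: list[GramianImage], layout: Layout | str) -> InputTensor:
    """Assemble five per-parameter images into one CNN input tensor.

    Requires exactly one image per parameter, all with the same field kind
    and indicator config.  ``concat_1d`` concatenates along the first
    (width) axis in the fixed channel order; ``stacked_5d`` stacks along
    depth.
    """
    layout = Layout(layout)
    if len(images) != len(CHANNEL_ORDER):
        raise ValueError(f"expected {len(CHANNEL_ORDER)} images, got {len(images)}")
    kinds = {img.field_kind for img in images}
    configs = {img.config for img in images}
    if len(kinds) != 1 or len(configs) != 1:
        raise ValueError("all images must share field kind and indicator config")
    by_param = {img.parameter: img for img in images}
    if set(by_param) != set(CHANNEL_ORDER):
        raise ValueError("need exactly one image per parameter")
    ordered = [by_param[p].matrix for p in CHANNEL_ORDER]
    if layout is Layout.CONCAT_1D:
        array = np.concatenate(ordered, axis=0)[:, :, None]
    else:
        array = np.stack(ordered, axis=-1)
    return InputTensor(
        array=np.ascontiguousarray(array, dtype=np.float32),
        layout=layout,
        field_kind=images[0].field_kind,
        config=images[0].config,
    )
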