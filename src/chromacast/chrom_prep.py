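"""Chromatogram preprocessing: baseline correction and log-concentration maps.

Raw LC-UV absorbance traces A(t) are baseline-corrected with a
sparsity-assisted estimator (low-pass baseline + sparse peaks with sparse
derivatives, solved by majorization-minimization), normalized by their
area under the curve into a unit-sum relative concentration profile C(t),
and mapped to the invertible log scale y*(t) = -log10(C + eps) / s used as
the CNN regression target.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla

__all__ = [
    "CANONICAL_N",
    "TIME_MAX_MIN",
    "Chromatogram",
    "ConcentrationProfile",
    "LogProfile",
    "BeadsParams",
    "read_chromatogram",
    "write_chromatogram",
    "beads_correct",
    "to_concentration",
    "log_transform",
    "inverse_log",
]

CANONICAL_N = 1501
TIME_MAX_MIN = 20.0


@dataclass
class Chromatogram:
    """UV absorbance vs elution time on a uniform grid."""

    time: np.ndarray        # minutes
    absorbance: np.ndarray  # arbitrary units
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.time.ndim != 1 or len(self.time) != len(self.absorbance):
            raise ValueError("time and absorbance must be aligned 1-d arrays")
        if len(self.time) < 3:
            raise ValueError("a chromatogram needs at least 3 points")
        dt = np.diff(self.time)
        if np.any(dt <= 0):
            raise ValueError("time grid must be strictly increasing")
        if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-12):
            raise ValueError("time grid must be uniform")

    @property
    def n_points(self) -> int:
        return len(self.time)

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0])


@dataclass
class ConcentrationProfile:
    """Relative % concentration profile C(t) (naringenin-equivalent scale)."""

    time: np.ndarray
    values: np.ndarray  # C(t) >= 0; sums to 1 when unit_area
    unit_area: bool = True
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0):
            raise ValueError("concentrations must be nonnegative")
        if self.unit_area and abs(self.values.sum() - 1.0) > 1e-9:
            raise ValueError("unit-area profile must sum to 1 within 1e-9")


@dataclass
class LogProfile:
    """Invertible log transform y*(t) of a concentration profile."""

    time: np.ndarray
    values: np.ndarray  # y*(t), order ~1e-1
    scale: float = 10.0
    floor: float = 1e-12
    meta: dict = field(default_factory=dict)


def canonical_grid(n: int = CANONICAL_N, t_max: float = TIME_MAX_MIN) -> np.ndarray:
    return np.linspace(0.0, t_max, n)


def read_chromatogram(
    path: str | Path, resample_to: int | None = None
) -> Chromatogram:
    """Read a ``time_min,absorbance`` CSV.

    With ``resample_to`` set, linearly interpolates onto a uniform grid of
    that many points spanning the original time range (endpoints preserved).
    """
    frame = pd.read_csv(path)
    if frame.shape[1] < 2:
        raise ValueError(f"{path}: expected columns time_min,absorbance")
    t = frame.iloc[:, 0].to_numpy(dtype=float)
    a = frame.iloc[:, 1].to_numpy(dtype=float)
    if np.any(np.diff(t) <= 0):
        raise ValueError(f"{path}: time column must be strictly increasing")
    if resample_to is not None:
        grid = np.linspace(t[0], t[-1], resample_to)
        a = np.interp(grid, t, a)
        t = grid
    return Chromatogram(time=t, absorbance=a, meta={"path": str(path)})


def write_chromatogram(c: Chromatogram, path: str | Path) -> None:
    pd.DataFrame({"time_min": c.time, "absorbance": c.absorbance}).to_csv(
        path, index=False
    )


# ---------------------------------------------------------------------------
# Sparsity-assisted baseline estimation (majorization-minimization).
#
# Model: y = x + f + w with x sparse-derivative peaks (nonnegative via an
# asymmetric penalty), f a low-pass baseline, w noise.  The baseline is
# recovered as f = LPF(y - x) once the peak signal x is estimated by
# minimizing
#   F(x) = 0.5 ||H(y - x)||^2 + lam0 sum theta(x) + sum_i lam_i ||phi(D_i x)||_1
# where H = B A^{-1} is a banded high-pass filter and theta is the
# asymmetric penalty theta(u) = u (u >= 0), -r u (u < 0).
# ---------------------------------------------------------------------------


@dataclass
class BeadsParams:
    """Hyperparameters of the baseline estimator.

    ``lam0/lam1/lam2`` are relative weights; they are multiplied by an
    amplitude scale derived from the signal (its robust peak height) so the
    defaults transfer across absorbance units.
    """

    filter_order: int = 1       # d: order of the zero-phase high-pass filter
    cutoff: float = 0.006       # fc: cutoff frequency, cycles/sample
    asymmetry: float = 6.0      # r: penalty ratio for negative excursions
    lam0: float = 0.001         # asymmetric amplitude penalty weight
    lam1: float = 0.01          # first-difference sparsity weight
    lam2: float = 0.01          # second-difference sparsity weight
    max_iter: int = 50
    tol: float = 1e-4           # relative cost change for convergence
    eps0: float = 1e-6
    eps1: float = 1e-6


def _ba_filters(d: int, fc: float, n: int) -> tuple[sp.spmatrix, sp.spmatrix]:
    """Banded A, B such that H = B A^{-1} is a zero-phase high-pass filter."""
    b = np.array([1.0, -1.0])
    for _ in range(d - 1):
        b = np.convolve(b, [-1.0, 2.0, -1.0])
    b = np.convolve(b, [-1.0, 1.0])
    omc = 2.0 * np.pi * fc
    t = ((1.0 - np.cos(omc)) / (1.0 + np.cos(omc))) ** d
    a = np.array([1.0])
    for _ in range(d):
        a = np.convolve(a, [1.0, 2.0, 1.0])
    a = b + t * a
    offsets = np.arange(-d, d + 1)
    A = sp.diags([a[i + d] for i in offsets], offsets, shape=(n, n), format="csc")
    B = sp.diags([b[i + d] for i in offsets], offsets, shape=(n, n), format="csc")
    return A, B


def beads_correct(
    c: Chromatogram, params: BeadsParams | None = None
) -> tuple[Chromatogram, Chromatogram]:
    """Estimate and remove the baseline drift of a chromatogram.

    Returns ``(corrected, baseline)`` with ``corrected = input - baseline``.
    Raises on non-convergence, carrying the per-iteration cost trace.
    """
    params = params or BeadsParams()
    y_orig = c.absorbance.astype(float)
    if len(y_orig) < 50:
        raise ValueError("baseline correction needs at least 50 points")
    # odd-reflection padding suppresses the high-pass filter's edge
    # transients; the pad is cropped before returning
    pad = min(len(y_orig) // 4, 300)
    left = 2.0 * y_orig[0] - y_orig[pad:0:-1]
    right = 2.0 * y_orig[-1] - y_orig[-2 : -pad - 2 : -1]
    y = np.concatenate([left, y_orig, right])
    n = len(y)
    # scale the relative penalty weights by a robust signal amplitude
    amp = float(np.percentile(y, 99) - np.percentile(y, 10))
    amp = amp if amp > 0 else max(float(np.abs(y).max()), 1.0)
    lam0, lam1, lam2 = params.lam0 * amp, params.lam1 * amp, params.lam2 * amp
    r, eps0, eps1 = params.asymmetry, params.eps0, params.eps1

    A, B = _ba_filters(params.filter_order, params.cutoff, n)
    A_lu = spla.splu(A)

    def high_pass(v: np.ndarray) -> np.ndarray:
        return B @ A_lu.solve(v)

    e = np.ones(n - 1)
    D1 = sp.diags([-e, e], [0, 1], shape=(n - 1, n), format="csr")
    e2 = np.ones(n - 2)
    D2 = sp.diags([e2, -2.0 * e2, e2], [0, 1, 2], shape=(n - 2, n), format="csr")
    D = sp.vstack([D1, D2], format="csr")
    BTB = (B.T @ B).tocsc()
    w = np.concatenate([lam1 * np.ones(n - 1), lam2 * np.ones(n - 2)])
    b_lin = (1.0 - r) / 2.0 * np.ones(n)
    d_vec = BTB @ A_lu.solve(y) - lam0 * (A.T @ b_lin)

    def theta(u: np.ndarray) -> float:
        return float(np.sum(np.where(u >= 0, u, -r * u)))

    def cost_of(x: np.ndarray) -> float:
        hp = high_pass(y - x)
        return (
            0.5 * float(hp @ hp)
            + lam0 * theta(x)
            + lam1 * float(np.sum(np.sqrt((D1 @ x) ** 2 + eps1)))
            + lam2 * float(np.sum(np.sqrt((D2 @ x) ** 2 + eps1)))
        )

    x = y.copy()
    trace: list[float] = []
    converged = False
    for _ in range(params.max_iter):
        dx = D @ x
        lam_diag = w / np.sqrt(dx * dx + eps1)
        gamma = (1.0 + r) / (4.0 * np.maximum(np.abs(x), eps0))
        M = 2.0 * lam0 * sp.diags(gamma) + D.T @ sp.diags(lam_diag) @ D
        system = (BTB + A.T @ M @ A).tocsc()
        x = A @ spla.spsolve(system, d_vec)
        trace.append(cost_of(x))
        if len(trace) > 1:
            prev, cur = trace[-2], trace[-1]
            if abs(prev - cur) <= params.tol * abs(prev):
                converged = True
                break
    if not converged:
        raise RuntimeError(
            f"baseline estimation did not converge in {params.max_iter} "
            f"iterations; cost trace: {trace}"
        )
    baseline = (y - x - high_pass(y - x))[pad : pad + len(y_orig)]
    corrected = y_orig - baseline
    meta = dict(c.meta)
    meta["beads_iterations"] = len(trace)
    return (
        Chromatogram(c.time.copy(), corrected, meta),
        Chromatogram(c.time.copy(), baseline, dict(c.meta)),
    )


def to_concentration(
    c: Chromatogram, response_factor: float | None = None
) -> ConcentrationProfile:
    """Area-normalize a baseline-corrected trace to a unit-sum C(t).

    Negative post-correction values are clipped to zero first.  The
    optional naringenin response factor is carried in ``meta`` for
    absolute quantification but never applied to the profile itself.
    """
    a = np.clip(c.absorbance, 0.0, None)
    total = a.sum()
    if total <= 0:
        raise ValueError("cannot normalize an all-zero chromatogram")
    meta = dict(c.meta)
    if response_factor is not None:
        meta["naringenin_response_factor"] = float(response_factor)
    return ConcentrationProfile(c.time.copy(), a / total, unit_area=True, meta=meta)


def log_transform(
    p: ConcentrationProfile, scale: float = 10.0, floor: float = 1e-12
) -> LogProfile:
    """Map C(t) to y*(t) = -log10(C + floor) / scale (order ~1e-1)."""
    y = -np.log10(p.values + floor) / scale
    return LogProfile(p.time.copy(), y, scale=scale, floor=floor, meta=dict(p.meta))


def inverse_log(l: LogProfile) -> ConcentrationProfile:
    """Invert :func:`log_transform`: C = 10^(-scale * y*) - floor."""
    c = np.power(10.0, -l.scale * l.values) - l.floor
    c = np.clip(c, 0.0, None)
    total = c.sum()
    unit = abs(total - 1.0) <= 1e-9
    return ConcentrationProfile(l.time.copy(), c, unit_area=unit, meta=dict(l.meta))
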