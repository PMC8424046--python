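"""Paired environment/chromatogram simulator with known ground truth.

Each synthetic plant gets a month of per-minute sensor channels whose
per-plant latent parameters (diurnal amplitude, cloudiness, watering decay,
pH mean-reversion, humidity coupling) shape both the channel statistics and
the *appearance* of the normalized series, so a CNN can recover them from
Gramian images.  Chromatogram peak amplitudes are a softplus-linear
function of standardized channel summary features times a per-solvent
factor, plus a slow baseline and detector noise.  The hidden weights and
peak table are returned for recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml
from scipy.signal import lfilter

from .chrom_prep import CANONICAL_N, TIME_MAX_MIN, Chromatogram, canonical_grid
from .rems_io import CHANNEL_ORDER, Parameter, SensorSeries

__all__ = [
    "SyntheticTruth",
    "PlantRecord",
    "SyntheticDataset",
    "default_truth",
    "gen_environment",
    "env_features",
    "gen_chromatogram",
    "gen_dataset",
]

MINUTES_PER_DAY = 1440

#: Per-solvent multiplicative amplitude masks (length = number of peaks).
#: E1 (methanol) extracts everything; E2/E3 progressively suppress the
#: more polar peaks, mimicking the dielectric-constant ordering.
_SOLVENT_MASKS = {
    "E1": np.array([1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0]),
    "E2": np.array([0.2, 0.9, 0.3, 1.0, 0.8, 0.2, 1.0, 0.6, 0.9, 0.4]),
    "E3": np.array([0.05, 0.3, 0.1, 0.6, 1.0, 0.05, 0.8, 0.3, 1.0, 0.15]),
}

#: Fixed environment-to-amplitude weight matrix (peaks x features), chosen
#: once and published here so synthetic runs are reproducible. Features are
#: standardized [sd(temp), sd(humidity), mean(light)/1e4, mean(moisture),
#: sd(pH)] summaries of the five channels.
_DEFAULT_WEIGHTS = 0.5 * np.array(
    [
        [+1.6, +0.4, -0.6, +0.3, -0.2],
        [-1.2, +1.1, +0.5, -0.4, +0.3],
        [+0.5, -1.4, +1.0, +0.6, -0.5],
        [-0.3, +0.6, -1.5, +1.2, +0.4],
        [+0.8, -0.5, +0.4, -1.3, +1.1],
        [-1.5, -0.8, +0.7, +0.5, +0.9],
        [+1.1, +1.3, -0.4, -0.6, -1.0],
        [-0.6, +0.5, +1.4, +0.8, +0.6],
        [+0.4, -1.0, -0.8, +1.5, -0.7],
        [+1.3, +0.7, +0.6, -0.5, +1.4],
    ]
)
_DEFAULT_BIAS = np.array([0.8, 0.5, 0.6, 0.4, 0.7, 0.3, 0.6, 0.5, 0.4, 0.6])


@dataclass
class SyntheticTruth:
    """Hidden generator state: peak table, weights, masks, noise levels."""

    peak_mu: np.ndarray      # retention times, minutes in (0, 20)
    peak_sigma: np.ndarray   # Gaussian widths, minutes
    weights: np.ndarray      # (n_peaks, 5) feature -> amplitude map
    bias: np.ndarray         # (n_peaks,)
    solvent_masks: dict[str, np.ndarray] = field(
        default_factory=lambda: {k: v.copy() for k, v in _SOLVENT_MASKS.items()}
    )
    feature_center: np.ndarray = field(
        default_factory=lambda: np.array([3.87, 7.86, 1.44, 0.46, 0.104])
    )
    feature_scale: np.ndarray = field(
        default_factory=lambda: np.array([1.10, 3.31, 0.23, 0.084, 0.05])
    )
    baseline_coeffs: tuple[float, float, float] = (0.05, 0.1, 0.02)
    noise_sd: float = 0.004
    replicate_cv: float = 0.05
    rt_jitter_sd: float = 0.12  # per-chromatogram retention-time shift, min
    seed: int = 0

    def __post_init__(self) -> None:
        self.peak_mu = np.asarray(self.peak_mu, dtype=float)
        self.peak_sigma = np.asarray(self.peak_sigma, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if np.any(self.peak_sigma <= 0):
            raise ValueError("peak widths must be positive")
        gaps = np.diff(np.sort(self.peak_mu))
        if gaps.size and gaps.min() < 3.0 * self.peak_sigma.max():
            raise ValueError("peaks must be separated by >= 3 max widths")

    @property
    def n_peaks(self) -> int:
        return len(self.peak_mu)

    def to_yaml(self, path) -> None:
        payload = {
            "peak_mu": self.peak_mu.tolist(),
            "peak_sigma": self.peak_sigma.tolist(),
            "weights": self.weights.tolist(),
            "bias": self.bias.tolist(),
            "solvent_masks": {k: v.tolist() for k, v in self.solvent_masks.items()},
            "feature_center": self.feature_center.tolist(),
            "feature_scale": self.feature_scale.tolist(),
            "baseline_coeffs": list(self.baseline_coeffs),
            "noise_sd": self.noise_sd,
            "replicate_cv": self.replicate_cv,
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh)


@dataclass
class PlantRecord:
    plant_id: str
    environment: dict[Parameter, SensorSeries]
    chromatograms: list[Chromatogram]
    latents: dict[str, float]
    features: np.ndarray


@dataclass
class SyntheticDataset:
    plants: list[PlantRecord]
    truth: SyntheticTruth

    @property
    def chromatograms(self) -> list[Chromatogram]:
        return [c for p in self.plants for c in p.chromatograms]


def default_truth(seed: int = 0, noise_sd: float = 0.004) -> SyntheticTruth:
    """The repo's fixed 10-peak truth (peak table is deterministic)."""
    peak_mu = np.array([1.6, 3.4, 5.1, 7.0, 8.8, 10.7, 12.5, 14.4, 16.3, 18.2])
    peak_sigma = np.array([0.10, 0.12, 0.09, 0.14, 0.11, 0.13, 0.10, 0.15, 0.12, 0.11])
    return SyntheticTruth(
        peak_mu=peak_mu,
        peak_sigma=peak_sigma,
        weights=_DEFAULT_WEIGHTS.copy(),
        bias=_DEFAULT_BIAS.copy(),
        noise_sd=noise_sd,
        seed=seed,
    )


def _ar1(rng: np.random.Generator, n: int, rho: float, sd: float) -> np.ndarray:
    eps = rng.normal(0.0, sd * np.sqrt(1.0 - rho * rho), n)
    return lfilter([1.0], [1.0, -rho], eps)


def _smooth_uniform(rng: np.random.Generator, n: int, window: int) -> np.ndarray:
    """Slowly varying noise in [0, 1] (moving average of uniforms)."""
    u = rng.uniform(0.0, 1.0, n + window)
    kernel = np.ones(window) / window
    sm = np.convolve(u, kernel, mode="valid")[:n]
    lo, hi = sm.min(), sm.max()
    return (sm - lo) / (hi - lo) if hi > lo else np.full(n, 0.5)


def _insert_missing(
    rng: np.random.Generator, n: int, missing_rate: float
) -> np.ndarray:
    """Seeded placement of contiguous outage blocks totaling ~missing_rate."""
    mask = np.zeros(n, dtype=bool)
    if missing_rate <= 0:
        return mask
    target = int(missing_rate * n)
    guard = 0
    while mask.sum() < target and guard < 10_000:
        guard += 1
        length = int(rng.integers(180, 1440))
        start = int(rng.integers(0, max(1, n - length)))
        mask[start : start + length] = True
    return mask


def gen_environment(
    days: int = 30,
    seed: int = 0,
    missing_rate: float = 0.0,
    latents: dict[str, float] | None = None,
) -> dict[Parameter, SensorSeries]:
    """Generate the five per-minute channels for one plant.

    Per-plant latents (drawn from ``seed`` unless given) control the
    diurnal amplitude of temperature, the humidity coupling, light
    cloudiness, the watering decay rate and the pH mean-reversion rate;
    they shape both the channel summary statistics and the normalized
    series' appearance.
    """
    if days < 2:
        raise ValueError("need at least 2 days")
    rng = np.random.default_rng(seed)
    n = days * MINUTES_PER_DAY
    t = np.arange(n, dtype=float)
    if latents is None:
        latents = {
            "temp_amplitude": float(rng.uniform(2.0, 8.0)),
            "humidity_coupling": float(rng.uniform(0.8, 3.0)),
            "cloudiness": float(rng.uniform(0.1, 0.9)),
            "watering_decay": float(rng.uniform(0.5, 4.0)),
            "ph_reversion": float(rng.uniform(0.002, 0.05)),
        }
    diurnal = np.sin(2.0 * np.pi * (t - 8.0 * 60.0) / MINUTES_PER_DAY)

    temp = 25.0 + latents["temp_amplitude"] * diurnal + _ar1(rng, n, 0.995, 1.2)
    hum = np.clip(
        70.0 - latents["humidity_coupling"] * (temp - 25.0) + _ar1(rng, n, 0.99, 1.5),
        0.0,
        100.0,
    )
    daylight = np.clip(np.sin(2.0 * np.pi * (t - 6.0 * 60.0) / MINUTES_PER_DAY), 0.0, None)
    clouds = _smooth_uniform(rng, n, 180)
    light = 60_000.0 * daylight * (1.0 - latents["cloudiness"] * clouds)
    light = np.clip(light + rng.normal(0.0, 200.0, n), 0.0, None)

    day_minute = t % MINUTES_PER_DAY
    since_watering = np.where(
        day_minute >= 8.0 * 60.0, day_minute - 8.0 * 60.0, day_minute + 16.0 * 60.0
    )
    moist = 0.2 + 0.6 * np.exp(
        -latents["watering_decay"] * since_watering / MINUTES_PER_DAY
    )
    moist = np.clip(moist + rng.normal(0.0, 0.01, n), 0.0, 1.0)

    theta = latents["ph_reversion"]
    ph_noise = lfilter([1.0], [1.0, -(1.0 - theta)], rng.normal(0.0, 0.02, n))
    ph = np.clip(6.5 + ph_noise, 4.0, 9.0)

    channels = {
        Parameter.TEMPERATURE: temp,
        Parameter.HUMIDITY: hum,
        Parameter.LIGHT: light,
        Parameter.SOIL_MOISTURE: moist,
        Parameter.SOIL_PH: ph,
    }
    out: dict[Parameter, SensorSeries] = {}
    for param in CHANNEL_ORDER:
        mask = _insert_missing(rng, n, missing_rate)
        values = channels[param].copy()
        values[mask] = np.nan
        out[param] = SensorSeries(
            parameter=param,
            timestamps=t.copy(),
            values=values,
            missing_mask=mask,
            regular=True,
            provenance={"latents": dict(latents)},
        )
    return out


def env_features(env: dict[Parameter, SensorSeries], truth: SyntheticTruth) -> np.ndarray:
    """Standardized channel summary feature vector z (length 5).

    Uses the observed cells only, so the features are well-defined for
    gappy series too: [sd(temp), sd(humidity), mean(light)/1e4,
    mean(moisture), sd(pH)], centered/scaled by the truth's constants.
    """
    raw = np.array(
        [
            np.nanstd(env[Parameter.TEMPERATURE].values),
            np.nanstd(env[Parameter.HUMIDITY].values),
            np.nanmean(env[Parameter.LIGHT].values) / 1e4,
            np.nanmean(env[Parameter.SOIL_MOISTURE].values),
            np.nanstd(env[Parameter.SOIL_PH].values),
        ]
    )
    return (raw - truth.feature_center) / truth.feature_scale


def _softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


def peak_amplitudes(
    features: np.ndarray, truth: SyntheticTruth, solvent: str
) -> np.ndarray:
    """a_j = softplus(W z + b) * solvent mask (all nonnegative)."""
    if solvent not in truth.solvent_masks:
        raise KeyError(f"unknown solvent {solvent!r}")
    return _softplus(truth.weights @ features + truth.bias) * truth.solvent_masks[solvent]


def gen_chromatogram(
    env: dict[Parameter, SensorSeries],
    truth: SyntheticTruth,
    solvent: str = "E1",
    seed: int = 0,
    n_points: int = CANONICAL_N,
) -> Chromatogram:
    """Emit one noisy chromatogram for an environment realization."""
    rng = np.random.default_rng(seed)
    time = canonical_grid(n_points)
    z = env_features(env, truth)
    amps = peak_amplitudes(z, truth, solvent)
    if truth.replicate_cv > 0:
        amps = amps * np.exp(rng.normal(0.0, truth.replicate_cv, amps.shape))
    # whole-run retention-time shift (column/temperature drift between runs)
    shift = rng.normal(0.0, truth.rt_jitter_sd) if truth.rt_jitter_sd > 0 else 0.0
    signal = np.zeros_like(time)
    for a, mu, sig in zip(amps, truth.peak_mu, truth.peak_sigma):
        signal += a * np.exp(-0.5 * ((time - (mu + shift)) / sig) ** 2)
    c0, c1, c2 = truth.baseline_coeffs
    baseline = c0 + c1 * time / TIME_MAX_MIN + c2 * np.sin(
        2.0 * np.pi * time / TIME_MAX_MIN
    )
    noise = rng.normal(0.0, truth.noise_sd, n_points) if truth.noise_sd > 0 else 0.0
    return Chromatogram(
        time=time,
        absorbance=signal + baseline + noise,
        meta={
            "solvent": solvent,
            "seed": seed,
            "true_amplitudes": amps,
            "features": z,
            "rt_shift": float(shift),
        },
    )


def gen_dataset(
    n_plants: int,
    truth: SyntheticTruth | None = None,
    seed: int = 0,
    solvents: tuple[str, ...] = ("E1", "E2", "E3"),
    replicates: int = 6,
    days: int = 30,
    missing_rate: float = 0.0,
) -> SyntheticDataset:
    """Per plant: one environment realization plus per-solvent replicates."""
    if n_plants < 2:
        raise ValueError("need at least 2 plants")
    truth = truth or default_truth(seed)
    plants = []
    for p in range(n_plants):
        env_seed = seed * 1_000_003 + p
        env = gen_environment(days=days, seed=env_seed, missing_rate=missing_rate)
        features = env_features(env, truth)
        chroms = []
        for si, solvent in enumerate(solvents):
            for rep in range(replicates):
                chrom_seed = env_seed * 97 + si * 13 + rep + 1
                chrom = gen_chromatogram(env, truth, solvent, seed=chrom_seed)
                chrom.meta.update(plant_id=f"plant{p:03d}", replicate=rep)
                chroms.append(chrom)
        plants.append(
            PlantRecord(
                plant_id=f"plant{p:03d}",
                environment=env,
                chromatograms=chroms,
                latents=dict(next(iter(env.values())).provenance["latents"]),
                features=features,
            )
        )
    return SyntheticDataset(plants=plants, truth=truth)
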