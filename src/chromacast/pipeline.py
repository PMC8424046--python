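"""End-to-end glue: dataset -> augmented pairs -> trained model -> metrics.

Kept separate from the click CLI so tests and the acceptance script can
drive the exact pipeline programmatically.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import chrom_prep, cnn_model, encoding, evaluation, imputation
from .chrom_prep import BeadsParams, Chromatogram, LogProfile
from .encoding import FieldKind, Layout
from .rems_io import CHANNEL_ORDER, Parameter, SensorSeries
from .synthetic_data import SyntheticDataset

__all__ = ["Pair", "prep_target", "encode_plant", "build_pairs", "evaluate_predictions"]


@dataclass
class Pair:
    """One augmented (input tensor, log-profile target) training pair."""

    tensor: np.ndarray
    target: np.ndarray
    time: np.ndarray
    plant_id: str
    solvent: str
    config: encoding.IndicatorConfig | None = None
    meta: dict = field(default_factory=dict)


def prep_target(
    chrom: Chromatogram,
    beads_params: BeadsParams | None = None,
    scale: float = 10.0,
    floor: float = 1e-5,
) -> LogProfile:
    """Raw trace -> baseline-corrected -> unit-area C(t) -> y*(t)."""
    corrected, _ = chrom_prep.beads_correct(chrom, beads_params)
    conc = chrom_prep.to_concentration(corrected)
    return chrom_prep.log_transform(conc, scale=scale, floor=floor)


def _prepare_channels(
    env: dict[Parameter, SensorSeries], imputed: bool, seed: int
) -> dict[Parameter, SensorSeries]:
    if not imputed:
        return env
    out = {}
    for param, series in env.items():
        if series.missing_mask.any():
            model = imputation.fit_stochastic_model(series)
            out[param] = imputation.impute(series, model, seed=seed)
        else:
            out[param] = series
    return out


def encode_plant(
    env: dict[Parameter, SensorSeries],
    k_grid: tuple[int, ...],
    d_grid: tuple[int, ...],
    layout: Layout = Layout.STACKED_5D,
    field_kind: FieldKind = FieldKind.GASF,
    indicators: tuple[encoding.Indicator, ...] = tuple(encoding.Indicator),
    imputed: bool = True,
    seed: int = 0,
) -> list[encoding.InputTensor]:
    """All augmented input tensors for one plant's environment."""
    channels = _prepare_channels(env, imputed, seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # k_max advisories on the big grid
        per_param = {
            param: encoding.augment(
                channels[param], k_grid, d_grid, field_kind, indicators
            )
            for param in CHANNEL_ORDER
        }
    n_combo = len(per_param[CHANNEL_ORDER[0]])
    tensors = []
    for i in range(n_combo):
        tensors.append(
            encoding.assemble_input([per_param[p][i] for p in CHANNEL_ORDER], layout)
        )
    return tensors


def build_pairs(
    dataset: SyntheticDataset,
    k_grid: tuple[int, ...] = (5, 60, 1440, 7200),
    d_grid: tuple[int, ...] = (720, 1440),
    layout: Layout = Layout.STACKED_5D,
    field_kind: FieldKind = FieldKind.GASF,
    indicators: tuple[encoding.Indicator, ...] = tuple(encoding.Indicator),
    imputed: bool = True,
    seed: int = 0,
    solvents: tuple[str, ...] | None = None,
    beads_params: BeadsParams | None = None,
    log_floor: float = 1e-5,
) -> list[Pair]:
    """Cross the augmented tensors of each plant with its prepped targets.

    Every augmented image of a plant is paired with that plant's (solvent,
    replicate) chromatogram targets — the many-to-one augmentation
    semantics of the training set.
    """
    pairs: list[Pair] = []
    for plant in dataset.plants:
        tensors = encode_plant(
            plant.environment, k_grid, d_grid, layout, field_kind, indicators,
            imputed=imputed, seed=seed,
        )
        for chrom in plant.chromatograms:
            if solvents is not None and chrom.meta.get("solvent") not in solvents:
                continue
            target = prep_target(chrom, beads_params, floor=log_floor)
            for tensor in tensors:
                pairs.append(
                    Pair(
                        tensor=tensor.array,
                        target=target.values.astype(np.float32),
                        time=target.time,
                        plant_id=plant.plant_id,
                        solvent=chrom.meta.get("solvent", "E1"),
                        config=tensor.config,
                        meta={"replicate": chrom.meta.get("replicate", 0)},
                    )
                )
    return pairs


def evaluate_predictions(
    model: cnn_model.TrainedModel,
    test_pairs: list[Pair],
    n_range: range = range(1, 11),
    tau: float = 1e-3,
    prominence_fraction: float = 0.05,
) -> dict:
    """Predict the held-out pairs and compute the full metric bundle."""
    xs = np.stack([p.tensor for p in test_pairs])
    preds = cnn_model.predict(model, xs)
    xcorrs, r2s, peak_samples = [], [], []
    for row, pair in enumerate(test_pairs):
        xcorrs.append(evaluation.cross_correlation(preds[row], pair.target))
        r2s.append(evaluation.r_squared(preds[row], pair.target))
        prom = prominence_fraction * float(np.ptp(pair.target))
        test_peaks = evaluation.detect_peaks(pair.time, -pair.target, prom, "test")
        pred_peaks = evaluation.detect_peaks(pair.time, -preds[row], prom, "predicted")
        peak_samples.append((pred_peaks, test_peaks))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        scan = evaluation.scan_tolerance(peak_samples, n_range=n_range, tau=tau)
    n_values = list(scan.n_values)
    mu_by_n = dict(zip(n_values, scan.mu_mcc))
    from scipy import stats

    # one-sample t-test of the metric distributions against 0
    p_xcorr = float(stats.ttest_1samp(xcorrs, 0.0, alternative="greater").pvalue)
    p_r2 = float(stats.ttest_1samp(r2s, 0.0, alternative="greater").pvalue)
    return {
        "n_test": len(test_pairs),
        "p_xcorr": p_xcorr,
        "p_r2": p_r2,
        "mean_xcorr": float(np.mean(xcorrs)),
        "sd_xcorr": float(np.std(xcorrs)),
        "mean_r2": float(np.mean(r2s)),
        "sd_r2": float(np.std(r2s)),
        "n_star": scan.n_star,
        "mu_mcc_1": float(mu_by_n[n_values[0]]),
        "mu_mcc_n_star": float(mu_by_n[scan.n_star]),
        "mu_mcc": {int(n): float(mu_by_n[n]) for n in n_values},
        "sigma_mcc": {int(n): float(s) for n, s in zip(n_values, scan.sigma_mcc)},
        "f": {int(n): float(v) for n, v in zip(n_values, scan.f)},
        "f_prime": {int(n): float(v) for n, v in zip(n_values, scan.f_prime)},
        "xcorr": [float(v) for v in xcorrs],
        "r2": [float(v) for v in r2s],
    }
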