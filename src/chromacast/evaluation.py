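"""Model evaluation: profile similarity metrics and peak-matching statistics.

Predicted and test chromatographic profiles are compared by (a) maximum
lagged cross-correlation, (b) the coefficient of determination of test
values regressed on predictions, and (c) a peak/non-peak contingency
summarized by the Matthews correlation coefficient MCC(n), where a
predicted peak counts as true when it falls within n combined Gaussian
widths of a test peak.  A tolerance scan selects the smallest n beyond
which the gain in mean MCC, relative to its spread, becomes negligible.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal, stats

__all__ = [
    "PeakSet",
    "MatchResult",
    "ToleranceScan",
    "MetricSummary",
    "cross_correlation",
    "r_squared",
    "detect_peaks",
    "match_peaks",
    "mcc",
    "scan_tolerance",
    "scan_from_mcc_table",
    "pr_auc",
    "cross_validate",
]

_FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))


@dataclass
class PeakSet:
    """Detected peaks of one profile: locations, heights and Gaussian widths."""

    locations: np.ndarray  # minutes, sorted
    heights: np.ndarray
    sigmas: np.ndarray     # Gaussian width estimate, minutes (> 0)
    source: str = "test"   # "test" or "predicted"
    grid_n: int = 0        # number of grid points of the originating profile

    def __post_init__(self) -> None:
        self.locations = np.asarray(self.locations, dtype=float)
        self.heights = np.asarray(self.heights, dtype=float)
        self.sigmas = np.asarray(self.sigmas, dtype=float)
        order = np.argsort(self.locations)
        self.locations = self.locations[order]
        self.heights = self.heights[order]
        self.sigmas = self.sigmas[order]
        if np.any(self.sigmas <= 0):
            raise ValueError("peak widths must be positive")

    def __len__(self) -> int:
        return len(self.locations)


@dataclass
class MatchResult:
    """Peak-classification contingency at tolerance multiplier n."""

    n: int
    tp: int
    fp: int
    fn: int
    grid_n: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("counts must be nonnegative")
        if self.tp + self.fp + self.fn > self.grid_n:
            raise ValueError("contingency exceeds the grid size")

    @property
    def tn(self) -> int:
        return self.grid_n - self.tp - self.fp - self.fn

    @property
    def mcc(self) -> float:
        return mcc(self)


@dataclass
class ToleranceScan:
    """Result of optimizing the peak-matching tolerance multiplier."""

    n_values: np.ndarray
    mu_mcc: np.ndarray
    sigma_mcc: np.ndarray
    f: np.ndarray            # mu / sigma, NaN where sigma == 0
    f_prime: np.ndarray      # forward differences of f (last entry NaN)
    n_star: int
    tau: float


@dataclass
class MetricSummary:
    """Per-stratum metric distribution (solvent label or fold id)."""

    stratum: str
    metrics: dict[str, np.ndarray] = field(default_factory=dict)

    def mean(self, name: str) -> float:
        return float(np.mean(self.metrics[name]))

    def sd(self, name: str) -> float:
        return float(np.std(self.metrics[name], ddof=1)) if len(self.metrics[name]) > 1 else 0.0


def cross_correlation(a: np.ndarray, b: np.ndarray, max_lag: int | None = None) -> float:
    """Maximum normalized cross-correlation over lags |l| <= max_lag.

    Both profiles are zero-meaned and unit-normed; the default lag window
    is a tenth of the profile length.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("profiles must be 1-d arrays of equal length")
    n = len(a)
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("cross-correlation is undefined for a constant profile")
    if max_lag is None:
        max_lag = n // 10
    a0 = a - a.mean()
    b0 = b - b.mean()
    a0 /= np.linalg.norm(a0)
    b0 /= np.linalg.norm(b0)
    full = signal.correlate(a0, b0, mode="full")
    center = n - 1
    lo, hi = center - max_lag, center + max_lag + 1
    return float(full[lo:hi].max())


def r_squared(pred: np.ndarray, test: np.ndarray) -> float:
    """Coefficient of determination of test values regressed on predictions."""
    pred = np.asarray(pred, dtype=float)
    test = np.asarray(test, dtype=float)
    if pred.shape != test.shape:
        raise ValueError("profiles must have equal length")
    if np.ptp(test) == 0:
        raise ValueError("R^2 is undefined for a constant test profile")
    if np.ptp(pred) == 0:
        return 0.0  # regression on a constant regressor explains nothing
    slope, intercept = np.polyfit(pred, test, 1)
    resid = test - (slope * pred + intercept)
    ss_res = float(resid @ resid)
    ss_tot = float(np.sum((test - test.mean()) ** 2))
    return 1.0 - ss_res / ss_tot


def detect_peaks(
    time: np.ndarray,
    values: np.ndarray,
    prominence: float,
    source: str = "test",
) -> PeakSet:
    """First-derivative local maxima filtered by prominence.

    Widths come from the full width at half prominence via
    sigma = FWHM / (2 sqrt(2 ln 2)); widths smaller than one grid step are
    floored at the grid spacing.
    """
    time = np.asarray(time, dtype=float)
    values = np.asarray(values, dtype=float)
    if len(values) < 3:
        raise ValueError("need at least 3 points to detect peaks")
    dt = float(time[1] - time[0])
    idx, props = signal.find_peaks(values, prominence=prominence)
    if len(idx) == 0:
        return PeakSet(np.empty(0), np.empty(0), np.empty(0), source, len(values))
    widths_samples = signal.peak_widths(values, idx, rel_height=0.5)[0]
    sigmas = np.maximum(widths_samples * dt * _FWHM_TO_SIGMA, dt)
    return PeakSet(time[idx], values[idx], sigmas, source, len(values))


def match_peaks(
    pred: PeakSet,
    test: PeakSet,
    n: int,
    grid_n: int | None = None,
    literal_eq1: bool = False,
) -> MatchResult:
    """Greedy one-to-one matching of predicted to test peaks.

    A predicted peak p' matches an unconsumed test peak p when
    |p' - p| <= n (sigma + sigma'); pairs are consumed in increasing
    distance order.  With ``literal_eq1`` the asymmetric printed rule
    p - n sigma <= p' + n sigma' <= p + n sigma is applied instead.
    Unmatched predicted peaks are FP, unmatched test peaks FN, and
    TN = grid_n - TP - FP - FN.
    """
    if n < 1:
        raise ValueError("tolerance multiplier n must be >= 1")
    grid_n = grid_n if grid_n is not None else (pred.grid_n or test.grid_n)
    if grid_n <= 0:
        raise ValueError("grid size must be positive")
    pairs = []
    for i, (p_loc, p_sig) in enumerate(zip(pred.locations, pred.sigmas)):
        for j, (t_loc, t_sig) in enumerate(zip(test.locations, test.sigmas)):
            if literal_eq1:
                ok = t_loc - n * t_sig <= p_loc + n * p_sig <= t_loc + n * t_sig
            else:
                ok = abs(p_loc - t_loc) <= n * (t_sig + p_sig)
            if ok:
                pairs.append((abs(p_loc - t_loc), i, j))
    pairs.sort()
    used_pred: set[int] = set()
    used_test: set[int] = set()
    for _, i, j in pairs:
        if i not in used_pred and j not in used_test:
            used_pred.add(i)
            used_test.add(j)
    tp = len(used_pred)
    fp = len(pred) - tp
    fn = len(test) - tp
    return MatchResult(n=n, tp=tp, fp=fp, fn=fn, grid_n=grid_n)


def mcc(m: MatchResult) -> float:
    """Matthews correlation coefficient of the peak contingency.

    (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)); returns 0 when
    any denominator factor vanishes.
    """
    tp, fp, fn, tn = m.tp, m.fp, m.fn, m.tn
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return float((tp * tn - fp * fn) / math.sqrt(denom))


def scan_from_mcc_table(
    mcc_table: np.ndarray, n_values: np.ndarray, tau: float = 1e-3
) -> ToleranceScan:
    """Select n* from a samples x tolerances MCC table.

    f(n) = mean/sd of MCC over samples; n* is the smallest scanned n whose
    forward difference f'(n) <= tau.  Tolerances where the sd vanishes are
    skipped with a warning; if no n qualifies the largest scanned n is
    returned with a warning.
    """
    mcc_table = np.asarray(mcc_table, dtype=float)
    n_values = np.asarray(n_values, dtype=int)
    if mcc_table.shape[0] < 2:
        raise ValueError("need at least 2 samples so the MCC spread is defined")
    mu = mcc_table.mean(axis=0)
    sigma = mcc_table.std(axis=0, ddof=1)
    f = np.full(len(n_values), np.nan)
    ok = sigma > 0
    if not ok.all():
        warnings.warn(
            "sigma_MCC vanished at some tolerances; f(n) undefined there",
            stacklevel=2,
        )
    f[ok] = mu[ok] / sigma[ok]
    f_prime = np.full(len(n_values), np.nan)
    for i in range(len(n_values) - 1):
        if ok[i] and ok[i + 1]:
            f_prime[i] = (f[i + 1] - f[i]) / (n_values[i + 1] - n_values[i])
    qualifying = [
        int(n_values[i])
        for i in range(len(n_values) - 1)
        if np.isfinite(f_prime[i]) and f_prime[i] <= tau
    ]
    if qualifying:
        n_star = qualifying[0]
    else:
        n_star = int(n_values[-1])
        warnings.warn(
            f"no tolerance reached f'(n) <= {tau}; returning the largest scanned n",
            stacklevel=2,
        )
    return ToleranceScan(
        n_values=n_values,
        mu_mcc=mu,
        sigma_mcc=sigma,
        f=f,
        f_prime=f_prime,
        n_star=n_star,
        tau=tau,
    )


def scan_tolerance(
    samples: list[tuple[PeakSet, PeakSet]],
    n_range: range = range(1, 11),
    tau: float = 1e-3,
    literal_eq1: bool = False,
) -> ToleranceScan:
    """MCC(n) per sample per tolerance, then n* selection (see Eq. 3 logic)."""
    if len(samples) < 2:
        raise ValueError("need at least 2 (pred, test) samples")
    n_values = np.array(list(n_range), dtype=int)
    table = np.empty((len(samples), len(n_values)))
    for si, (pred, test) in enumerate(samples):
        for ni, n in enumerate(n_values):
            table[si, ni] = mcc(match_peaks(pred, test, int(n), literal_eq1=literal_eq1))
    return scan_from_mcc_table(table, n_values, tau)


def pr_auc(
    samples: list[tuple[np.ndarray, np.ndarray, PeakSet]],
    n: int,
    threshold_grid: np.ndarray,
    literal_eq1: bool = False,
) -> float:
    """Area under the pooled precision-recall curve of peak detection.

    ``samples`` are (time, predicted profile, test PeakSet) triples.  The
    detection prominence threshold is swept over ``threshold_grid``; at
    each threshold TP/FP/FN are pooled across samples.  The trapezoid rule
    is applied over recall-sorted points with the (recall 0, precision 1)
    anchor prepended and, when the curve does not reach recall 1, a
    (recall 1, precision 0) endpoint appended.
    """
    threshold_grid = np.sort(np.asarray(threshold_grid, dtype=float))
    if len(threshold_grid) < 2:
        raise ValueError("need at least 2 thresholds")
    points = []
    any_peaks = False
    for thr in threshold_grid:
        tp = fp = fn = 0
        for time, pred_profile, test_peaks in samples:
            detected = detect_peaks(time, pred_profile, prominence=thr, source="predicted")
            if len(detected):
                any_peaks = True
            res = match_peaks(detected, test_peaks, n, literal_eq1=literal_eq1)
            tp, fp, fn = tp + res.tp, fp + res.fp, fn + res.fn
        if tp + fp == 0 or tp + fn == 0:
            continue
        points.append((tp / (tp + fn), tp / (tp + fp)))  # (recall, precision)
    if not any_peaks or not points:
        raise ValueError("no peaks detected at any threshold")
    points.sort()
    recalls = [0.0] + [p[0] for p in points]
    precisions = [1.0] + [p[1] for p in points]
    if recalls[-1] < 1.0:
        recalls.append(1.0)
        precisions.append(0.0)
    return float(np.trapezoid(precisions, recalls))


def _default_train_fn(train_records):
    """Train the package CNN with a small smoke-scale config."""
    from . import cnn_model

    config = cnn_model.ModelConfig(epochs=2)
    model = cnn_model.train(config, train_records)
    return lambda xs: cnn_model.predict(model, xs)


def cross_validate(
    records: list,
    train_fn=None,
    folds: int = 60,
    seed: int = 0,
    stratify_by_solvent: bool = True,
    n_tolerance: int = 1,
    prominence: float | None = None,
):
    """Randomized k-fold cross-validation with per-solvent stratified summaries.

    ``records`` are objects with ``tensor`` (model input), ``time``,
    ``target`` (log profile values) and ``solvent`` attributes.
    ``train_fn(train_records)`` must return a callable mapping a batch of
    input arrays to predicted profiles; the default trains the package CNN
    per fold.  Returns ``(summaries, ttests)``: per-stratum
    :class:`MetricSummary` objects pooled over folds plus one-tailed
    two-sample t-tests between solvent strata means.
    """
    if train_fn is None:
        train_fn = _default_train_fn
    n_rec = len(records)
    if folds < 2 or n_rec // folds < 1:
        raise ValueError("each fold needs at least 1 record and folds >= 2")
    if n_rec / folds < 2:
        warnings.warn("folds contain fewer than 2 records each", stacklevel=2)
    rng = np.random.default_rng(seed)
    order = rng.permutation(n_rec)
    fold_of = np.zeros(n_rec, dtype=int)
    for pos, rec_idx in enumerate(order):
        fold_of[rec_idx] = pos % folds
    per_fold: list[MetricSummary] = []
    per_solvent: dict[str, dict[str, list[float]]] = {}
    for fold in range(folds):
        test_idx = np.flatnonzero(fold_of == fold)
        train_idx = np.flatnonzero(fold_of != fold)
        model = train_fn([records[i] for i in train_idx])
        xs = np.stack([records[i].tensor for i in test_idx])
        preds = model(xs)
        summary = MetricSummary(stratum=f"fold{fold}")
        vals: dict[str, list[float]] = {"xcorr": [], "r2": [], "mcc": []}
        for row, i in enumerate(test_idx):
            rec = records[i]
            xc = cross_correlation(preds[row], rec.target)
            r2 = r_squared(preds[row], rec.target)
            prom = prominence
            if prom is None:
                prom = 0.05 * float(np.ptp(rec.target))
            test_peaks = detect_peaks(rec.time, -rec.target, prom, "test")
            pred_peaks = detect_peaks(rec.time, -preds[row], prom, "predicted")
            m = mcc(match_peaks(pred_peaks, test_peaks, n_tolerance))
            vals["xcorr"].append(xc)
            vals["r2"].append(r2)
            vals["mcc"].append(m)
            if stratify_by_solvent:
                bucket = per_solvent.setdefault(
                    rec.solvent, {"xcorr": [], "r2": [], "mcc": []}
                )
                bucket["xcorr"].append(xc)
                bucket["r2"].append(r2)
                bucket["mcc"].append(m)
        summary.metrics = {k: np.array(v) for k, v in vals.items()}
        per_fold.append(summary)
    summaries = per_fold
    ttests: dict[tuple[str, str, str], float] = {}
    if stratify_by_solvent:
        for solvent, vals in sorted(per_solvent.items()):
            s = MetricSummary(stratum=solvent)
            s.metrics = {k: np.array(v) for k, v in vals.items()}
            summaries.append(s)
        solvents = sorted(per_solvent)
        for a_i in range(len(solvents)):
            for b_i in range(len(solvents)):
                if a_i == b_i:
                    continue
                a, b = solvents[a_i], solvents[b_i]
                for metric in ("xcorr", "r2", "mcc"):
                    res = stats.ttest_ind(
                        per_solvent[a][metric],
                        per_solvent[b][metric],
                        equal_var=False,
                        alternative="greater",
                    )
                    ttests[(a, b, metric)] = float(res.pvalue)
    return summaries, ttests
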