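import math

import numpy as np
import pytest
from types import SimpleNamespace

from chromacast.evaluation import (
    MatchResult,
    PeakSet,
    cross_correlation,
    cross_validate,
    detect_peaks,
    match_peaks,
    mcc,
    pr_auc,
    r_squared,
    scan_from_mcc_table,
    scan_tolerance,
)

from conftest import gaussian_mix


def peak_set(locations, sigma=0.1, source="test", grid_n=1501):
    locations = np.asarray(locations, dtype=float)
    return PeakSet(
        locations=locations,
        heights=np.ones_like(locations),
        sigmas=np.full_like(locations, sigma),
        source=source,
        grid_n=grid_n,
    )


def brute_mcc(tp, fp, fn, tn):
    """Independent direct-formula oracle."""
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / math.sqrt(denom)


class TestCrossCorrelation:
    def test_identical_is_one(self, grid_1501):
        a = gaussian_mix(grid_1501, [(5, 0.2, 1.0), (12, 0.3, 0.7)])
        assert cross_correlation(a, a) == pytest.approx(1.0)

    def test_negation_is_minus_one_at_lag_zero(self, grid_1501):
        a = gaussian_mix(grid_1501, [(5, 0.2, 1.0)])
        assert cross_correlation(a, -a, max_lag=0) == pytest.approx(-1.0)

    def test_shift_invariance(self, grid_1501):
        a = gaussian_mix(grid_1501, [(5, 0.2, 1.0), (12, 0.3, 0.7)])
        b = np.roll(a, 5)
        # small deviation from 1 comes from the 5 wrapped-around samples
        assert cross_correlation(a, b) == pytest.approx(1.0, abs=1e-3)
        assert cross_correlation(a, b) > cross_correlation(a, b, max_lag=0)

    def test_constant_errors(self):
        with pytest.raises(ValueError):
            cross_correlation(np.ones(100), np.arange(100.0))


class TestRSquared:
    def test_equal_is_one(self, rng):
        y = rng.normal(0, 1, 200)
        assert r_squared(y, y) == pytest.approx(1.0)

    def test_constant_prediction_is_zero(self, rng):
        y = rng.normal(0, 1, 200)
        assert r_squared(np.full(200, y.mean()), y) == 0.0

    def test_offset_absorbed(self, rng):
        y = rng.normal(0, 1, 200)
        assert r_squared(y + 3.7, y) == pytest.approx(1.0)

    def test_constant_test_errors(self, rng):
        with pytest.raises(ValueError):
            r_squared(rng.normal(0, 1, 50), np.ones(50))


class TestDetectPeaks:
    def test_single_gaussian(self, grid_1501):
        a = gaussian_mix(grid_1501, [(10.0, 0.2, 1.0)])
        ps = detect_peaks(grid_1501, a, prominence=0.1)
        assert len(ps) == 1
        dt = grid_1501[1] - grid_1501[0]
        assert abs(ps.locations[0] - 10.0) <= dt
        assert ps.sigmas[0] == pytest.approx(0.2, rel=0.10)

    def test_monotone_is_empty(self, grid_1501):
        ps = detect_peaks(grid_1501, np.linspace(0, 1, 1501), prominence=0.01)
        assert len(ps) == 0

    def test_two_gaussians(self, grid_1501):
        a = gaussian_mix(grid_1501, [(8.0, 0.2, 1.0), (10.0, 0.2, 0.8)])
        ps = detect_peaks(grid_1501, a, prominence=0.1)
        assert len(ps) == 2


class TestMatchPeaks:
    def test_exact_match(self):
        p = peak_set([3.0, 7.0, 12.0])
        res = match_peaks(p, p, n=1)
        assert (res.tp, res.fp, res.fn) == (3, 0, 0)
        assert res.tn == 1501 - 3

    def test_tolerance_boundary(self):
        test = peak_set([10.0], sigma=0.2)
        pred = peak_set([10.5], sigma=0.2, source="predicted")
        res1 = match_peaks(pred, test, n=1)  # 0.5 > 1*(0.2+0.2)
        assert (res1.tp, res1.fp, res1.fn) == (0, 1, 1)
        res2 = match_peaks(pred, test, n=2)  # 0.5 <= 2*(0.2+0.2)
        assert (res2.tp, res2.fp, res2.fn) == (1, 0, 0)

    def test_empty_prediction(self):
        test = peak_set([3.0, 7.0, 12.0])
        pred = peak_set([], source="predicted")
        res = match_peaks(pred, test, n=1)
        assert (res.tp, res.fp, res.fn) == (0, 0, 3)

    def test_one_to_one_greedy(self):
        # two predictions near one test peak: only one may match
        test = peak_set([10.0], sigma=0.3)
        pred = peak_set([9.9, 10.1], sigma=0.3, source="predicted")
        res = match_peaks(pred, test, n=1)
        assert (res.tp, res.fp, res.fn) == (1, 1, 0)

    def test_swap_symmetry(self, rng):
        for _ in range(20):
            a = peak_set(np.sort(rng.uniform(0, 20, 5)), sigma=0.15)
            b = peak_set(np.sort(rng.uniform(0, 20, 7)), sigma=0.15, source="predicted")
            ab = match_peaks(b, a, n=2)
            ba = match_peaks(a, b, n=2)
            assert ab.tp == ba.tp
            assert (ab.fp, ab.fn) == (ba.fn, ba.fp)

    def test_tp_monotone_in_n(self, rng):
        test = peak_set(np.linspace(1, 19, 10), sigma=0.1)
        jitter = rng.normal(0, 0.25, 10)
        pred = peak_set(np.sort(np.linspace(1, 19, 10) + jitter), sigma=0.1,
                        source="predicted")
        results = [match_peaks(pred, test, n) for n in range(1, 11)]
        tps = [r.tp for r in results]
        fns = [r.fn for r in results]
        assert all(a <= b for a, b in zip(tps, tps[1:]))
        assert all(a >= b for a, b in zip(fns, fns[1:]))

    def test_literal_eq1_switch(self):
        test = peak_set([10.0], sigma=0.4)
        pred = peak_set([9.0], sigma=0.05, source="predicted")
        # printed rule: p - n*sigma <= p' + n*sigma' <= p + n*sigma
        # 9.6 <= 9.05 is false -> no match under the literal reading
        lit = match_peaks(pred, test, n=1, literal_eq1=True)
        assert lit.tp == 0
        # symmetric overlap: |9 - 10| = 1 > 0.45 -> also no match at n=1
        sym = match_peaks(pred, test, n=1)
        assert sym.tp == 0
        # at n=3: literal 8.8 <= 9.15 <= 11.2 -> match
        assert match_peaks(pred, test, n=3, literal_eq1=True).tp == 1


class TestMcc:
    def test_perfect(self):
        assert mcc(MatchResult(1, tp=10, fp=0, fn=0, grid_n=1501)) == 1.0

    def test_hand_arithmetic(self):
        res = MatchResult(1, tp=90, fp=10, fn=10, grid_n=1000)
        assert res.tn == 890
        assert mcc(res) == pytest.approx(80000.0 / 90000.0)

    def test_perfectly_wrong(self):
        # TP = TN = 0 with FP, FN > 0
        res = MatchResult(1, tp=0, fp=30, fn=20, grid_n=50)
        assert res.tn == 0
        assert mcc(res) == -1.0

    def test_zero_factor_gives_zero(self):
        assert mcc(MatchResult(1, tp=0, fp=0, fn=5, grid_n=100)) == 0.0

    def test_brute_force_grid(self):
        for tp in range(0, 13, 3):
            for fp in range(0, 13, 3):
                for fn in range(0, 13, 3):
                    for tn in range(0, 13, 3):
                        res = MatchResult(1, tp=tp, fp=fp, fn=fn,
                                          grid_n=tp + fp + fn + tn)
                        assert mcc(res) == pytest.approx(brute_mcc(tp, fp, fn, tn))

    def test_matches_sklearn_style_confusion(self, rng):
        """Dual route: per-point label vectors fed to an independent formula."""
        for _ in range(50):
            n = int(rng.integers(10, 50))
            tp = int(rng.integers(0, 5))
            fp = int(rng.integers(0, 5))
            fn = int(rng.integers(0, 5))
            if tp + fp + fn > n:
                continue
            tn = n - tp - fp - fn
            y_true = np.array([1] * tp + [1] * fn + [0] * fp + [0] * tn)
            y_pred = np.array([1] * tp + [0] * fn + [1] * fp + [0] * tn)
            num = np.cov(y_true, y_pred, bias=True)[0, 1]
            den = y_true.std() * y_pred.std()
            expected = num / den if den > 0 else 0.0
            got = mcc(MatchResult(1, tp=tp, fp=fp, fn=fn, grid_n=n))
            assert got == pytest.approx(expected, abs=1e-12)


class TestToleranceScan:
    def _table_for_f(self, f_values):
        """Two-sample MCC table with sd == 1 and mean == f at each n."""
        f = np.asarray(f_values, dtype=float)
        c = 1.0 / np.sqrt(2.0)
        return np.vstack([f + c, f - c])

    def test_hand_constructed_f(self):
        f = [1.0, 1.5, 1.6, 1.601]
        scan = scan_from_mcc_table(self._table_for_f(f), np.arange(1, 5), tau=1e-2)
        assert scan.n_star == 3
        assert np.allclose(scan.f[: len(f)], f)

    def test_no_qualifying_n_warns_and_returns_max(self):
        f = [1.0, 2.0, 3.0, 4.0]
        with pytest.warns(UserWarning, match="largest"):
            scan = scan_from_mcc_table(self._table_for_f(f), np.arange(1, 5), tau=1e-3)
        assert scan.n_star == 4

    def test_degenerate_sd_warns(self):
        table = np.ones((3, 4))  # identical pred/test: sd == 0 everywhere
        with pytest.warns(UserWarning):
            scan = scan_from_mcc_table(table, np.arange(1, 5), tau=1e-3)
        assert np.isnan(scan.f).all()

    @pytest.mark.parametrize("seed", range(10))
    def test_saturating_f_property(self, seed):
        rng = np.random.default_rng(seed)
        # monotone saturating sequence: increments decay geometrically
        inc = rng.uniform(0.5, 1.0) * 0.5 ** np.arange(10)
        f = np.cumsum(inc)
        tau = float(inc[rng.integers(2, 8)])  # somewhere inside the range
        scan = scan_from_mcc_table(self._table_for_f(f), np.arange(1, 11), tau=tau)
        i = scan.n_star - 1
        assert scan.f_prime[i] <= tau
        if i > 0:
            assert scan.f_prime[i - 1] > tau

    def test_scan_tolerance_end_to_end(self, rng):
        samples = []
        for _ in range(6):
            locs = np.linspace(2, 18, 8)
            test = peak_set(locs, sigma=0.08)
            pred = peak_set(np.sort(locs + rng.normal(0, 0.3, 8)), sigma=0.08,
                            source="predicted")
            samples.append((pred, test))
        scan = scan_tolerance(samples, n_range=range(1, 11), tau=1e-3)
        assert 1 <= scan.n_star <= 10
        # mu_MCC must be non-decreasing for jittered same-count peak sets
        assert np.all(np.diff(scan.mu_mcc) >= -1e-12)

    def test_needs_two_samples(self):
        with pytest.raises(ValueError):
            scan_tolerance([(peak_set([5.0]), peak_set([5.0]))])


class TestPrAuc:
    def test_perfect_predictor(self, grid_1501):
        profile = gaussian_mix(grid_1501, [(5, 0.2, 1.0), (12, 0.2, 0.8)])
        test_peaks = detect_peaks(grid_1501, profile, prominence=0.05)
        samples = [(grid_1501, profile, test_peaks)]
        auc = pr_auc(samples, n=1, threshold_grid=np.linspace(0.05, 0.5, 8))
        assert auc == pytest.approx(1.0)

    def test_half_precision_recall(self, grid_1501):
        # prediction hits one of two test peaks and adds one spurious peak:
        # pooled precision = recall = 0.5 at every threshold -> AUC = 0.5
        test_profile = gaussian_mix(grid_1501, [(5, 0.2, 1.0), (10, 0.2, 1.0)])
        pred_profile = gaussian_mix(grid_1501, [(5, 0.2, 1.0), (15, 0.2, 1.0)])
        test_peaks = detect_peaks(grid_1501, test_profile, prominence=0.05)
        samples = [(grid_1501, pred_profile, test_peaks)]
        auc = pr_auc(samples, n=1, threshold_grid=np.linspace(0.05, 0.5, 8))
        assert auc == pytest.approx(0.5)

    def test_grid_order_invariant(self, grid_1501, rng):
        profile = gaussian_mix(grid_1501, [(5, 0.2, 1.0), (12, 0.2, 0.4)])
        test_peaks = detect_peaks(grid_1501, profile, prominence=0.05)
        pred = gaussian_mix(grid_1501, [(5.05, 0.2, 1.0), (12.5, 0.2, 0.4)])
        samples = [(grid_1501, pred, test_peaks)]
        grid = np.linspace(0.05, 0.9, 9)
        a = pr_auc(samples, n=2, threshold_grid=grid)
        b = pr_auc(samples, n=2, threshold_grid=rng.permutation(grid))
        assert a == pytest.approx(b)

    def test_needs_thresholds(self, grid_1501):
        with pytest.raises(ValueError):
            pr_auc([], n=1, threshold_grid=np.array([0.1]))


def _mean_predictor(records):
    mean = np.mean([r.target for r in records], axis=0)
    return lambda xs: np.tile(mean, (len(xs), 1))


def _make_records(rng, n, solvent, noise_sd, grid):
    base = gaussian_mix(grid, [(5, 0.2, 1.0), (12, 0.3, 0.8)])
    records = []
    for _ in range(n):
        target = base + rng.normal(0, noise_sd, len(grid))
        records.append(
            SimpleNamespace(
                tensor=np.zeros((2, 2), dtype=np.float32),
                time=grid,
                target=target,
                solvent=solvent,
            )
        )
    return records


class TestCrossValidate:
    def test_two_folds_disjoint(self, rng, grid_1501):
        records = _make_records(rng, 10, "E1", 0.01, grid_1501)
        summaries, _ = cross_validate(
            records, _mean_predictor, folds=2, seed=0, stratify_by_solvent=False
        )
        folds = [s for s in summaries if s.stratum.startswith("fold")]
        assert len(folds) == 2
        assert sum(len(s.metrics["xcorr"]) for s in folds) == 10

    def test_seed_reproducible(self, rng, grid_1501):
        records = _make_records(rng, 8, "E1", 0.01, grid_1501)
        a, _ = cross_validate(records, _mean_predictor, folds=2, seed=3,
                              stratify_by_solvent=False)
        b, _ = cross_validate(records, _mean_predictor, folds=2, seed=3,
                              stratify_by_solvent=False)
        for sa, sb in zip(a, b):
            assert np.array_equal(sa.metrics["xcorr"], sb.metrics["xcorr"])

    def test_solvent_separation(self, rng, grid_1501):
        clean = _make_records(rng, 24, "E1", 0.002, grid_1501)
        noisy = _make_records(rng, 24, "E3", 0.2, grid_1501)
        summaries, ttests = cross_validate(
            clean + noisy, _mean_predictor, folds=4, seed=0,
            stratify_by_solvent=True,
        )
        by_stratum = {s.stratum: s for s in summaries}
        assert by_stratum["E1"].mean("xcorr") > by_stratum["E3"].mean("xcorr")
        assert ttests[("E1", "E3", "xcorr")] < 0.05

    def test_fold_too_small_errors(self, rng, grid_1501):
        records = _make_records(rng, 4, "E1", 0.01, grid_1501)
        with pytest.raises(ValueError):
            cross_validate(records, _mean_predictor, folds=8, seed=0)
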