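"""Drift summaries, repeatability records, and exact nonparametric tests."""

from itertools import permutations, product

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import ivimdrift as iv
from ivimdrift.containers import ImageSeries, IVIMMaps
from ivimdrift.driftstats import (
    drift_first_last, drift_slope, friedman_exact, repeatability,
    select_representative, signed_rank_exact,
)


def uniform_series(scheme, profile, shape=(6, 6, 4)):
    n = np.arange(len(scheme), dtype=float)
    data = np.broadcast_to(profile(n), shape + (len(scheme),)).copy()
    return ImageSeries(data, scheme)


class TestDriftFirstLast:
    def test_arithmetic(self):
        """First median 100, last 98, 450 s apart -> -4/3 % per 5 min."""
        s = iv.scheme.protocol_preset("diffusive")
        idx = s.b0_indices
        assert s.t[idx[-1]] - s.t[idx[0]] == pytest.approx(375.0)

        def profile(n):
            v = np.full_like(n, 100.0)
            ramp = (n - idx[0]) / (idx[-1] - idx[0])
            return v - 2.0 * np.clip(ramp, 0, 1)

        series = uniform_series(s, profile)
        ds = drift_first_last(series, series.mask)
        expected = 100.0 * (98.0 / 100.0 - 1.0) * 300.0 / 375.0
        assert ds.value == pytest.approx(expected, abs=1e-9)

    def test_drift_free_is_zero(self, diffusive_scheme):
        series = uniform_series(diffusive_scheme, lambda n: np.full_like(n, 50.0))
        assert drift_first_last(series, series.mask).value == 0.0

    def test_constructed_uniform_drift(self, phantom, diffusive_scheme):
        """A purely temporal +4 %/5 min field is recovered by the metric."""
        clean = iv.synthdata.forward_signal(phantom.maps, diffusive_scheme,
                                            "diffusive", phantom.mask)
        model = iv.driftcorr.SpatiotemporalDriftModel(
            np.zeros((3, 3, 3, 3)), np.zeros(3), np.ones(3))
        model.coefficients[0, 0, 0, 0] = 1.0
        rate_per_n = 0.04 * diffusive_scheme.volume_interval / 300.0
        model.coefficients[1, 0, 0, 0] = rate_per_n
        drifted = iv.synthdata.apply_drift(clean, model)
        ds = drift_first_last(drifted, phantom.mask)
        assert ds.value == pytest.approx(4.0, abs=0.1)


class TestDriftSlope:
    def test_b0_slope(self, diffusive_scheme):
        series = uniform_series(diffusive_scheme,
                                lambda n: 100.0 - 0.02 * n * 7.5)
        ds = drift_slope(series, series.mask, 0.0)
        assert ds.value == pytest.approx(-6.0, rel=1e-6)

    def test_direction_intercepts_absorb_offsets(self, sivim_scheme):
        """Per-direction offsets with a common temporal trend: the shared
        slope is recovered exactly."""
        n = np.arange(len(sivim_scheme), dtype=float)
        t = sivim_scheme.t
        offsets = {d: 90.0 + 5.0 * i for i, d in enumerate(
            iv.scheme.CANONICAL_DIRECTIONS)}
        vals = np.zeros(len(sivim_scheme))
        for i, a in enumerate(sivim_scheme.acquisitions):
            base = offsets[a.direction] if a.direction else 100.0
            vals[i] = base - 0.01 * t[i]
        series = ImageSeries(np.broadcast_to(
            vals, (4, 4, 2, len(sivim_scheme))).copy(), sivim_scheme)
        ds = drift_slope(series, series.mask, 200.0)
        mean_intercept = np.mean([offsets[d] for d in
                                  iv.scheme.CANONICAL_DIRECTIONS])
        expected = 100.0 * (-0.01) * 300.0 / mean_intercept
        assert ds.value == pytest.approx(expected, rel=1e-6)

    def test_constant_signal_zero_slope(self, sivim_scheme):
        series = uniform_series(sivim_scheme, lambda n: np.full_like(n, 80.0))
        assert drift_slope(series, series.mask, 0.0).value \
            == pytest.approx(0.0, abs=1e-10)

    def test_agrees_with_first_last_for_linear_drift(self, diffusive_scheme):
        series = uniform_series(diffusive_scheme,
                                lambda n: 100.0 * (1.0 - 0.0002 * n * 7.5))
        a = drift_first_last(series, series.mask).value
        b = drift_slope(series, series.mask, 0.0).value
        assert abs(a - b) <= 0.1 * abs(b)


class TestRepeatability:
    def _maps(self, val):
        shape = (4, 4, 2)
        return IVIMMaps(D=np.full(shape, val), f=np.full(shape, val / 10.0))

    def test_arithmetic_and_symmetry(self):
        m1, m2 = self._maps(0.68), self._maps(0.70)
        rois = {"PFWM": np.ones((4, 4, 2), dtype=bool)}
        recs = repeatability(m1, m2, rois)
        d = {r.parameter: r for r in recs}
        assert d["D"].average == pytest.approx(0.69)
        assert d["D"].abs_difference == pytest.approx(0.02)
        swapped = {r.parameter: r for r in repeatability(m2, m1, rois)}
        assert swapped["D"].average == d["D"].average
        assert swapped["D"].abs_difference == d["D"].abs_difference

    def test_identical_reps(self):
        m = self._maps(0.7)
        recs = repeatability(m, m, {"CS": np.ones((4, 4, 2), dtype=bool)})
        assert all(r.abs_difference == 0.0 for r in recs)

    def test_empty_roi_error(self):
        m1, m2 = self._maps(0.6), self._maps(0.6)
        m1.D[:] = np.nan
        with pytest.raises(ValueError, match="empty"):
            repeatability(m1, m2, {"CB": np.ones((4, 4, 2), dtype=bool)})


def friedman_oracle(values):
    """Brute-force enumeration of all (k!)^n within-block permutations."""
    values = np.asarray(values, float)
    n, k = values.shape
    ranks = np.vstack([sps.rankdata(r) for r in values])

    def stat(rk):
        R = rk.sum(axis=0)
        return 12.0 / (n * k * (k + 1)) * np.sum(R ** 2) - 3.0 * n * (k + 1)

    obs = stat(ranks)
    perms = list(permutations(range(k)))
    cnt = tot = 0
    for combo in product(perms, repeat=n):
        rk = np.vstack([ranks[i][list(p)] for i, p in enumerate(combo)])
        tot += 1
        if stat(rk) >= obs - 1e-9:
            cnt += 1
    return obs, cnt / tot


class TestFriedmanExact:
    def test_concordant_example(self):
        res = friedman_exact(np.array([[1, 2, 3]] * 3, float))
        assert res.statistic == pytest.approx(6.0)
        assert res.p_exact == pytest.approx(6 / 216)

    def test_constant_table(self):
        res = friedman_exact(np.ones((4, 3)))
        assert res.statistic == pytest.approx(0.0)
        assert res.p_exact == 1.0

    def test_matches_oracle_battery(self):
        rng = np.random.default_rng(42)
        for trial in range(30):
            n = int(rng.integers(2, 5))
            if trial % 3 == 0:
                vals = rng.integers(0, 3, (n, 3)).astype(float)
            else:
                vals = rng.normal(size=(n, 3))
            res = friedman_exact(vals)
            so, po = friedman_oracle(vals)
            assert res.statistic == pytest.approx(so, abs=1e-9)
            assert res.p_exact == pytest.approx(po, abs=1e-12)

    def test_k2_reduces_to_sign_test(self):
        """For k = 2 the exact p equals the two-sided binomial tail."""
        rng = np.random.default_rng(5)
        vals = rng.normal(size=(6, 2))
        res = friedman_exact(vals)
        wins = int(np.sum(vals[:, 0] > vals[:, 1]))
        n = vals.shape[0]
        extreme = max(wins, n - wins)
        p_binom = sum(sps.binom.pmf(j, n, 0.5)
                      for j in range(n + 1)
                      if max(j, n - j) >= extreme)
        assert res.p_exact == pytest.approx(p_binom, abs=1e-12)

    def test_invariance_to_block_order_and_relabeling(self):
        rng = np.random.default_rng(8)
        vals = rng.normal(size=(4, 3))
        base = friedman_exact(vals)
        shuffled = friedman_exact(vals[::-1, [2, 0, 1]])
        assert shuffled.statistic == pytest.approx(base.statistic)
        assert shuffled.p_exact == pytest.approx(base.p_exact)

    def test_chi2_bridge(self):
        """Sanity bridge on null data at n = 20: the exact permutation p
        tracks the chi-square approximation (the exact null is discrete,
        so pointwise gaps of a few percent remain)."""
        rng = np.random.default_rng(17)
        diffs = []
        for _ in range(20):
            vals = rng.normal(size=(20, 3))
            exact = friedman_exact(vals, cap=10 ** 16)
            approx = float(sps.chi2.sf(exact.statistic, 2))
            diffs.append(abs(exact.p_exact - approx))
        assert max(diffs) < 0.1
        assert np.median(diffs) < 0.05

    def test_cap_fallback(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(size=(20, 3))
        res = friedman_exact(vals)  # (3!)^20 >> cap
        assert res.method == "friedman-chi2-approx"
        with pytest.raises(ValueError):
            friedman_exact(vals, fallback=False)


def signed_rank_oracle(x, y):
    d = np.asarray(x, float) - np.asarray(y, float)
    d = d[d != 0]
    r = sps.rankdata(np.abs(d))
    T = r.sum()
    W = r[d > 0].sum()
    obs = abs(W - T / 2)
    cnt = sum(1 for signs in product([0, 1], repeat=len(d))
              if abs(sum(ri for ri, s in zip(r, signs) if s) - T / 2)
              >= obs - 1e-9)
    return W, cnt / 2 ** len(d)


class TestSignedRankExact:
    def test_all_positive_five_pairs(self):
        res = signed_rank_exact([1, 2, 3, 4, 5], [0, 0.5, 1.2, 2, 2.5])
        assert res.p_exact == pytest.approx(2 / 32)

    def test_all_zero_differences(self):
        with pytest.raises(ValueError, match="zero"):
            signed_rank_exact([1, 2], [1, 2])

    def test_antisymmetry(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(size=8), rng.normal(size=8)
        a = signed_rank_exact(x, y)
        b = signed_rank_exact(y, x)
        assert a.p_exact == pytest.approx(b.p_exact, abs=1e-12)

    def test_matches_oracle_battery(self):
        rng = np.random.default_rng(99)
        for trial in range(30):
            n = int(rng.integers(3, 11))
            x, y = rng.normal(size=n), rng.normal(size=n)
            if trial % 4 == 0:
                x, y = np.round(x, 1), np.round(y, 1)
            if not np.any(x - y):
                continue
            res = signed_rank_exact(x, y)
            Wo, po = signed_rank_oracle(x, y)
            assert res.statistic == pytest.approx(Wo)
            assert res.p_exact == pytest.approx(po, abs=1e-12)


class TestSelectRepresentative:
    def _table(self, entries):
        return pd.DataFrame(entries,
                            columns=["subject", "repetition", "roi", "scan",
                                     "value"])

    def test_single_candidate(self):
        t = self._table([(1, 1, "PFWM", "s", -3.0)])
        assert select_representative(t) == (1, 1)

    def test_exact_median_subject_wins(self):
        rows = []
        for subj, v in ((1, -4.0), (2, -2.0), (3, 0.0)):
            for roi in ("PFWM", "CB"):
                rows.append((subj, 1, roi, "diffusive", v))
        assert select_representative(self._table(rows)) == (2, 1)

    def test_brute_force_rank_sums(self):
        rng = np.random.default_rng(21)
        rows = []
        for subj in (1, 2, 3):
            for rep in (1, 2):
                for roi in ("PFWM", "CS", "CB"):
                    rows.append((subj, rep, roi, "s",
                                 float(rng.normal())))
        t = self._table(rows)
        pivot = t.pivot_table(index=["subject", "repetition"],
                              columns=["roi", "scan"], values="value")
        dist = (pivot - pivot.median()).abs()
        scores = dist.rank(axis=0).sum(axis=1)
        assert select_representative(t) == min(
            scores.index[scores == scores.min()])

    def test_empty(self):
        with pytest.raises(ValueError):
            select_representative(pd.DataFrame())
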