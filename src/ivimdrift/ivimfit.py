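"""IVIM parameter estimation.

Signals are first directionally averaged with a geometric average (the
log-domain arithmetic mean), which mitigates background-gradient cross
terms; the flow-compensated and non-flow-compensated scans of the
ballistic protocol are each normalized by their masked median b = 0 signal
before being combined.  Three protocol-specific estimators are provided:

* sIVIM: closed-form segmented solution from one b = 0 and two b > 0
  volumes — D from the log-signal ratio, intercept A, then f = 1 - A/S0.
* diffusive: per-voxel bounded nonlinear least squares of the
  biexponential S(b) = S0·((1-f)·e^{-bD} + f·e^{-bD*}).
* ballistic: per-voxel bounded nonlinear least squares of
  S(b,c) = S0·((1-f)·e^{-bD} + f·e^{-bD_b}·e^{-c²v_d²}) with the blood
  diffusivity D_b fixed (default 1.75 µm²/ms).

Voxels where a fit fails are set to NaN and excluded from ROI statistics
downstream.  Root-mean-square residual maps quantify goodness of fit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from . import models
from .containers import ImageSeries, IVIMMaps

__all__ = [
    "AveragedSeries",
    "FitResult",
    "geometric_average",
    "normalize_fc_nc",
    "fit_sivim",
    "fit_diffusive",
    "fit_ballistic",
    "residual_map",
    "DIFFUSIVE_BOUNDS",
    "BALLISTIC_BOUNDS",
]

logger = logging.getLogger(__name__)

#: Default parameter bounds; D and D* in µm²/ms, v_d in mm/s.
DIFFUSIVE_BOUNDS = {"D": (0.1, 3.5), "Dstar": (5.0, 100.0), "f": (0.0, 0.5)}
BALLISTIC_BOUNDS = {"D": (0.1, 3.5), "v_d": (0.0, 10.0), "f": (0.0, 0.5)}


@dataclass
class AveragedSeries:
    """Direction-averaged series: one volume per unique (scan, b, c)."""

    data: np.ndarray          # (X, Y, Z, M)
    b: np.ndarray             # (M,) s/mm²
    c: np.ndarray             # (M,) s/mm
    scan_ids: list[str]
    n_mean: np.ndarray        # (M,) mean original acquisition index
    mask: np.ndarray
    voxel_size: tuple[float, float, float] = (2.0, 2.0, 5.0)

    def __post_init__(self) -> None:
        keys = list(zip(self.scan_ids, self.b, self.c))
        if len(set(keys)) != len(keys):
            raise ValueError("averaged volumes must be unique by (scan, b, c)")
        if np.any(self.data < 0):
            raise ValueError("averaged data must be nonnegative")


@dataclass
class FitResult:
    """Parameter maps plus per-voxel RMS residual and fit metadata."""

    maps: IVIMMaps
    residual_rms: np.ndarray
    regime: str
    valid: np.ndarray
    meta: dict = field(default_factory=dict)


def geometric_average(series: ImageSeries, floor: float = 1e-12
                      ) -> AveragedSeries:
    """Geometric mean over acquisitions sharing (scan, b, c).

    Zero/negative signals inside the mask are floored to ``floor`` with a
    warning (the geometric mean is undefined at 0).
    """
    scheme = series.scheme
    keys = list(zip(scheme.scan_ids, scheme.b, scheme.c))
    groups: dict[tuple, list[int]] = {}
    for i, k in enumerate(keys):
        groups.setdefault(k, []).append(i)
    order = sorted(groups)

    n_floored = int(np.sum(series.data[series.mask] < floor))
    if n_floored:
        logger.warning("geometric average: flooring %d nonpositive signal "
                       "value(s) to %g", n_floored, floor)
    logdata = np.log(np.maximum(series.data, floor))

    vols, bs, cs, scans, nmean = [], [], [], [], []
    for key in order:
        idx = groups[key]
        vols.append(np.exp(logdata[..., idx].mean(axis=-1)))
        scans.append(key[0]); bs.append(key[1]); cs.append(key[2])
        nmean.append(float(np.mean(idx)))
    return AveragedSeries(np.stack(vols, axis=-1), np.array(bs), np.array(cs),
                          scans, np.array(nmean), series.mask.copy(),
                          series.voxel_size)


def normalize_fc_nc(fc: AveragedSeries, nc: AveragedSeries,
                    mask: np.ndarray | None = None) -> AveragedSeries:
    """Normalize each scan by its masked median b = 0 signal and combine."""
    halves = []
    for part in (fc, nc):
        m = part.mask if mask is None else mask
        b0 = np.flatnonzero(part.b == 0)
        if b0.size == 0:
            raise ValueError("missing b = 0 volume")
        ref = np.median(part.data[m][:, b0])
        if ref <= 0:
            raise ValueError("nonpositive median b = 0 signal")
        halves.append(part.data / ref)
    # tag the halves so (scan, b, c) keys stay unique even if the two
    # inputs carry identical scan labels
    return AveragedSeries(
        np.concatenate(halves, axis=-1),
        np.concatenate([fc.b, nc.b]),
        np.concatenate([fc.c, nc.c]),
        [f"FC|{s}" for s in fc.scan_ids] + [f"NC|{s}" for s in nc.scan_ids],
        np.concatenate([fc.n_mean, nc.n_mean]),
        (fc.mask if mask is None else mask).copy(),
        fc.voxel_size,
    )


def _finish(maps: IVIMMaps, avg: AveragedSeries, regime: str,
            valid: np.ndarray, meta: dict) -> FitResult:
    res = FitResult(maps, np.full(avg.data.shape[:3], np.nan), regime,
                    valid, meta)
    res.residual_rms = residual_map(avg, res)
    return res


def fit_sivim(avg: AveragedSeries) -> FitResult:
    """Closed-form segmented sIVIM estimation from three averaged b-values."""
    b0 = np.flatnonzero(avg.b == 0)
    bpos = np.flatnonzero(avg.b > 0)
    if b0.size != 1 or bpos.size != 2:
        raise ValueError("sIVIM needs exactly one b = 0 and two b > 0 "
                         "volumes after averaging")
    bpos = bpos[np.argsort(avg.b[bpos])]
    b1, b2 = avg.b[bpos] * models.B_TO_MS_PER_UM2
    S0 = avg.data[..., b0[0]]
    S1 = avg.data[..., bpos[0]]
    S2 = avg.data[..., bpos[1]]

    valid = avg.mask & (S0 > 0) & (S1 > 0) & (S2 > 0)
    n_invalid = int(avg.mask.sum() - valid.sum())
    if n_invalid:
        logger.warning("sIVIM: %d voxel(s) with nonpositive signal marked "
                       "invalid", n_invalid)

    with np.errstate(divide="ignore", invalid="ignore"):
        D = (np.log(S1) - np.log(S2)) / (b2 - b1)
        A = S1 * np.exp(b1 * D)
        f = 1.0 - A / S0
    n_clipped = int(np.sum((f[valid] < 0) | (f[valid] > 1)))
    if n_clipped:
        logger.info("sIVIM: clipping f outside [0, 1] in %d voxel(s) "
                    "(%.2f%% of mask)", n_clipped,
                    100.0 * n_clipped / max(valid.sum(), 1))
    f = np.clip(f, 0.0, 1.0)
    for m in (D, A, f):
        m[~valid] = np.nan
    maps = IVIMMaps(D=D, f=f, A=A, S0=np.where(valid, S0, np.nan))
    return _finish(maps, avg, "sivim", valid,
                   {"n_invalid": n_invalid, "n_clipped_f": n_clipped})


def _segmented_init(bvals, sig, b_threshold):
    """Monoexponential log-linear fit on b >= b_threshold -> (D, A)."""
    sel = bvals >= b_threshold
    x = bvals[sel] * models.B_TO_MS_PER_UM2
    y = np.log(np.maximum(sig[sel], 1e-12))
    slope, intercept = np.polyfit(x, y, 1)
    return max(-slope, 1e-3), np.exp(intercept)


def _nls_map(avg: AveragedSeries, residual_fun, x0_fun, lb, ub, param_names,
             regime, meta_extra=None, max_nfev: int = 200):
    shape = avg.data.shape[:3]
    out = {p: np.full(shape, np.nan) for p in param_names}
    valid = np.zeros(shape, dtype=bool)
    n_fail = 0
    iters = []
    for vox in np.argwhere(avg.mask):
        sig = avg.data[tuple(vox)]
        if not np.all(np.isfinite(sig)) or sig.max() <= 0:
            n_fail += 1
            continue
        x0 = x0_fun(sig)
        x0 = np.clip(x0, lb + 1e-12, ub - 1e-12)
        try:
            res = least_squares(residual_fun, x0, args=(sig,),
                                bounds=(lb, ub), method="trf",
                                ftol=1e-12, xtol=1e-12, gtol=1e-12,
                                max_nfev=max_nfev)
        except Exception:
            n_fail += 1
            continue
        if not np.all(np.isfinite(res.x)):
            n_fail += 1
            continue
        for p, v in zip(param_names, res.x):
            out[p][tuple(vox)] = v
        valid[tuple(vox)] = True
        iters.append(res.nfev)
    if n_fail:
        logger.warning("%s fit: %d voxel(s) failed and were marked invalid",
                       regime, n_fail)
    meta = {"n_failed": n_fail,
            "mean_nfev": float(np.mean(iters)) if iters else 0.0,
            "bounds": {p: (float(l), float(u))
                       for p, l, u in zip(param_names, lb, ub)}}
    if meta_extra:
        meta.update(meta_extra)
    return out, valid, meta


def fit_diffusive(avg: AveragedSeries,
                  bounds: dict | None = None) -> FitResult:
    """Bounded NLS of the diffusive biexponential, segmented initialization.

    Initial values: monoexponential fit on b >= 200 s/mm² gives D and the
    intercept A, f = 1 - A/S(0), D* starts at 10 µm²/ms.  D* estimates
    hitting the lower bound (default 5 µm²/ms) are reported as-is.
    """
    if np.unique(avg.b).size < 4:
        raise ValueError("diffusive fit needs >= 4 distinct b-values")
    bnd = dict(DIFFUSIVE_BOUNDS)
    if bounds:
        bnd.update(bounds)
    bvals = avg.b
    s0_idx = int(np.argmin(bvals))
    smax = float(np.nanmax(avg.data))
    lb = np.array([1e-9, bnd["f"][0], bnd["D"][0], bnd["Dstar"][0]])
    ub = np.array([10.0 * smax, bnd["f"][1], bnd["D"][1], bnd["Dstar"][1]])

    def resid(x, sig):
        S0, f, D, Dstar = x
        return models.signal_diffusive(bvals, S0, f, D, Dstar) - sig

    def x0(sig):
        D_init, A = _segmented_init(bvals, sig, 200.0)
        s_b0 = max(sig[s0_idx], 1e-12)
        f_init = 1.0 - A / s_b0
        return np.array([s_b0, f_init, D_init, 10.0])

    out, valid, meta = _nls_map(avg, resid, x0, lb, ub,
                                ("S0", "f", "D", "Dstar"), "diffusive")
    maps = IVIMMaps(D=out["D"], f=out["f"], Dstar=out["Dstar"], S0=out["S0"])
    return _finish(maps, avg, "diffusive", valid, meta)


def fit_ballistic(avg: AveragedSeries, D_b: float = models.BLOOD_DIFFUSIVITY,
                  bounds: dict | None = None) -> FitResult:
    """Bounded NLS of the ballistic representation with fixed D_b.

    Requires a combined series with both flow-compensated (c = 0) and
    non-flow-compensated (c > 0) volumes; initialization comes from a
    segmented monoexponential fit on the c = 0 subset.
    """
    if not (np.any(avg.c > 0) and np.any(avg.c == 0)):
        raise ValueError("ballistic fit needs both c = 0 and c > 0 volumes "
                         "(v_d is unidentifiable otherwise)")
    pairs = {(b, c) for b, c in zip(avg.b, avg.c)}
    if len(pairs) < 4:
        raise ValueError("ballistic fit needs >= 4 distinct (b, c) pairs")
    bnd = dict(BALLISTIC_BOUNDS)
    if bounds:
        bnd.update(bounds)
    bvals, cvals = avg.b, avg.c
    fc_sel = cvals == 0
    s0_idx = int(np.argmin(np.where(fc_sel, bvals, np.inf)))
    b_init_thr = np.quantile(bvals[fc_sel & (bvals > 0)], 0.5)
    smax = float(np.nanmax(avg.data))
    lb = np.array([1e-9, bnd["f"][0], bnd["D"][0], bnd["v_d"][0]])
    ub = np.array([10.0 * smax, bnd["f"][1], bnd["D"][1], bnd["v_d"][1]])

    def resid(x, sig):
        S0, f, D, v_d = x
        return models.signal_ballistic(bvals, cvals, S0, f, D, v_d, D_b) - sig

    def x0(sig):
        D_init, A = _segmented_init(
            np.where(fc_sel, bvals, -1.0), sig, b_init_thr)
        s_b0 = max(sig[s0_idx], 1e-12)
        f_init = 1.0 - A / s_b0
        return np.array([s_b0, f_init, D_init, 1.0])

    out, valid, meta = _nls_map(avg, resid, x0, lb, ub,
                                ("S0", "f", "D", "v_d"), "ballistic",
                                {"D_b": D_b})
    maps = IVIMMaps(D=out["D"], f=out["f"], v_d=out["v_d"], S0=out["S0"])
    return _finish(maps, avg, "ballistic", valid, meta)


def predict(maps: IVIMMaps, b: np.ndarray, c: np.ndarray, regime: str,
            D_b: float = models.BLOOD_DIFFUSIVITY) -> np.ndarray:
    """Model signals (X, Y, Z, M) for fitted maps at the given (b, c)."""
    shape = maps.shape
    out = np.empty(shape + (len(b),))
    if regime == "sivim":
        S0, A, D = maps.S0, maps.A, maps.D
        for k in range(len(b)):
            out[..., k] = np.where(b[k] == 0, S0,
                                   models.signal_monoexp(b[k], A, D))
    elif regime == "diffusive":
        for k in range(len(b)):
            out[..., k] = models.signal_diffusive(
                b[k], maps.S0, maps.f, maps.D, maps.Dstar)
    elif regime == "ballistic":
        for k in range(len(b)):
            out[..., k] = models.signal_ballistic(
                b[k], c[k], maps.S0, maps.f, maps.D, maps.v_d, D_b)
    else:
        raise ValueError(f"unknown regime {regime!r}")
    return out


def residual_map(avg: AveragedSeries, fit: FitResult) -> np.ndarray:
    """Per-voxel RMS difference between model fit and averaged data."""
    model = predict(fit.maps, avg.b, avg.c, fit.regime,
                    fit.meta.get("D_b", models.BLOOD_DIFFUSIVITY))
    rms = np.sqrt(np.mean((model - avg.data) ** 2, axis=-1))
    rms[~fit.valid] = np.nan
    return rms
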