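"""Synthetic brain-like IVIM phantoms, forward signals, drift and noise.

The phantom is an ellipsoidal "brain" with piecewise-smooth IVIM parameter
maps in healthy-brain ranges (D 0.6–1.0 µm²/ms, f 1–6%, D* 5–30 µm²/ms,
v_d 0.5–3 mm/s) and three disjoint cubic ROIs placed at spatial extremes
that mimic prefrontal white matter (anterior), centrum semiovale
(superior-central) and cerebellum (posterior-inferior).  Forward signals
follow the mono-/biexponential IVIM representations; drift is superimposed
as a multiplicative field from the same second-order spatiotemporal
polynomial family the correction estimates, and noise is Rician by default
(magnitude MRI).
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
from scipy.ndimage import gaussian_filter

from . import models
from .containers import ImageSeries, IVIMMaps, Phantom, ROI_NAMES
from .driftcorr import SpatiotemporalDriftModel, apply_inverse
from .scheme import AcquisitionScheme

__all__ = [
    "PARAMETER_RANGES",
    "make_phantom",
    "forward_signal",
    "make_drift_model",
    "apply_drift",
    "add_noise",
    "sigma_for_snr",
]

#: Brain-like value ranges for the generated maps (units as in IVIMMaps).
PARAMETER_RANGES: dict[str, tuple[float, float]] = {
    "D": (0.6, 1.0),
    "f": (0.01, 0.06),
    "Dstar": (5.0, 30.0),
    "v_d": (0.5, 3.0),
    "S0": (500.0, 1500.0),
}

#: Aliases for the drift-spec pole names, mapped to ROI labels.
_POLE_ALIASES = {
    "frontal": "PFWM", "anterior": "PFWM", "pfwm": "PFWM",
    "central": "CS", "superior": "CS", "cs": "CS",
    "inferior": "CB", "posterior": "CB", "cerebellum": "CB", "cb": "CB",
}


def _smooth_field(rng: np.random.Generator, shape, lo: float, hi: float,
                  sigma: float = 3.0) -> np.ndarray:
    """Smooth random field rescaled exactly onto [lo, hi]."""
    g = gaussian_filter(rng.standard_normal(shape), sigma=sigma)
    g = (g - g.min()) / max(g.max() - g.min(), np.finfo(float).tiny)
    return lo + g * (hi - lo)


def _roi_slices(center: np.ndarray, half: np.ndarray) -> tuple[slice, ...]:
    return tuple(slice(int(round(c - h)), int(round(c + h)) + 1)
                 for c, h in zip(center, half))


def make_phantom(shape: tuple[int, int, int] = (32, 32, 8),
                 seed: int = 0,
                 voxel_size: tuple[float, float, float] = (2.0, 2.0, 5.0)
                 ) -> Phantom:
    """Deterministic brain-like phantom on the given grid.

    Axes follow the RAS convention used throughout: x left–right,
    y posterior–anterior, z inferior–superior.
    """
    shape = tuple(int(s) for s in shape)
    if len(shape) != 3 or any(s < 8 for s in shape):
        raise ValueError("phantom shape must be 3D with every dimension >= 8")
    rng = np.random.default_rng(seed)

    center = (np.array(shape) - 1) / 2.0
    semi = 0.47 * np.array(shape)
    ijk = np.indices(shape, dtype=float)
    r2 = sum(((ijk[k] - center[k]) / semi[k]) ** 2 for k in range(3))
    mask = r2 <= 1.0

    maps = {}
    for name, (lo, hi) in PARAMETER_RANGES.items():
        m = _smooth_field(rng, shape, lo, hi)
        m[~mask] = 0.0
        maps[name] = m

    # Cubic ROIs at the anterior, superior-central and posterior-inferior
    # poles (PFWM / CS / CB analogues), fully inside the ellipsoid.
    half = np.maximum(1, np.array(shape) // 16)
    roi_centers = {
        1: center + np.array([0.0, 0.60 * semi[1], 0.0]),            # PFWM
        2: center + np.array([0.0, 0.0, 0.55 * semi[2]]),            # CS
        3: center + np.array([0.0, -0.50 * semi[1], -0.40 * semi[2]]),  # CB
    }
    roi_labels = np.zeros(shape, dtype=int)
    for lab, c in roi_centers.items():
        sl = _roi_slices(c, half)
        if not mask[sl].all():
            raise ValueError(f"ROI {ROI_NAMES[lab]} does not fit in the mask")
        if np.any(roi_labels[sl] != 0):
            raise ValueError("overlapping ROIs")
        roi_labels[sl] = lab

    ivim = IVIMMaps(D=maps["D"], f=maps["f"], Dstar=maps["Dstar"],
                    v_d=maps["v_d"], S0=maps["S0"])
    return Phantom(ivim, mask, roi_labels, voxel_size)


def forward_signal(maps: IVIMMaps, scheme: AcquisitionScheme, regime: str,
                   mask: np.ndarray | None = None,
                   D_b: float = models.BLOOD_DIFFUSIVITY) -> ImageSeries:
    """Noiseless, drift-free forward signals for a scheme.

    regime "diffusive" and "sivim" use the biexponential diffusive form
    (so the segmented sIVIM estimator's bias can be studied on it);
    "ballistic" uses the flow-encoding form with fixed blood diffusivity.
    """
    regime = regime.lower()
    need = {"sivim": ("S0", "f", "D", "Dstar"),
            "diffusive": ("S0", "f", "D", "Dstar"),
            "ballistic": ("S0", "f", "D", "v_d")}
    if regime not in need:
        raise ValueError(f"unknown regime {regime!r}")
    for field in need[regime]:
        if getattr(maps, field) is None:
            raise ValueError(f"regime {regime!r} requires map {field!r}")

    b = scheme.b
    if np.any(b < 0):
        raise ValueError("negative b-value in scheme")
    c = scheme.c
    data = np.empty(maps.shape + (len(scheme),))
    for k in range(len(scheme)):
        if regime == "ballistic":
            data[..., k] = models.signal_ballistic(
                b[k], c[k], maps.S0, maps.f, maps.D, maps.v_d, D_b)
        else:
            data[..., k] = models.signal_diffusive(
                b[k], maps.S0, maps.f, maps.D, maps.Dstar)
    return ImageSeries(data, scheme, mask)


def make_drift_model(spec: Mapping[str, float], phantom: Phantom,
                     scheme: AcquisitionScheme,
                     temporal_curvature: float = 0.3
                     ) -> SpatiotemporalDriftModel:
    """Construct an in-family drift model hitting target drift rates at poles.

    ``spec`` maps pole names ("frontal"/"PFWM", "central"/"CS",
    "inferior"/"CB") to target drift rates in % per 5 min.  The returned
    multiplicative field F(n; x,y,z) equals 1 at n = 0 for all voxels and
    its end-of-scan drift, 100·(F(n_last) - 1)·300/t_last evaluated at each
    pole's ROI centroid, equals the target exactly.  ``temporal_curvature``
    is the fraction of the end-of-scan drift carried by the quadratic
    temporal term (0 = purely linear in time).

    The spatial profile is affine (within the second-order family), so
    antisymmetric pole targets yield near-zero whole-mask median drift.
    """
    if not spec:
        raise ValueError("empty drift spec")
    if not 0.0 <= temporal_curvature <= 1.0:
        raise ValueError("temporal_curvature must be in [0, 1]")
    for rate in spec.values():
        if abs(rate) > 20.0:
            raise ValueError(f"drift magnitude {rate} exceeds ±20 %/5 min")

    ijk = np.argwhere(phantom.mask)
    bbox_min = ijk.min(axis=0).astype(float)
    bbox_max = ijk.max(axis=0).astype(float)
    span = np.where(bbox_max > bbox_min, bbox_max - bbox_min, 1.0)

    poles, rates = [], []
    for name, rate in spec.items():
        roi = _POLE_ALIASES.get(name.lower(), name.upper())
        centroid = np.argwhere(phantom.roi_mask(roi)).mean(axis=0)
        poles.append(2.0 * (centroid - bbox_min) / span - 1.0)
        rates.append(float(rate))
    P = np.array(poles)
    r = np.array(rates)

    # Affine rate profile r(X, Y, Z) = c0 + c1·X + c2·Y + c3·Z through the
    # pole constraints (minimum-norm when underdetermined).
    A = np.column_stack([np.ones(len(P)), P])
    coef, *_ = np.linalg.lstsq(A, r, rcond=None)
    if np.max(np.abs(A @ coef - r)) > 1e-9 * max(1.0, np.max(np.abs(r))):
        raise ValueError("inconsistent pole constraints: spec unreachable "
                         "with an affine spatial profile")

    n_last = len(scheme) - 1
    if n_last < 1:
        raise ValueError("scheme too short for a drift model")
    dt = scheme.volume_interval
    u_last = n_last * dt / 300.0  # scan length in units of 5 min

    # The pole constraints leave free directions in the affine profile; use
    # them to flatten the masked median b = 0 signal trajectory, so that
    # pole drift is a genuinely spatial effect invisible to a whole-mask
    # (global) summary rather than an artifact of how the S0 texture
    # happens to correlate with the drift gradient.
    null = _null_space(A)
    if null.shape[1] and np.any(r) and phantom.maps.S0 is not None:
        coef = _flatten_median_signal(coef, null, phantom, scheme,
                                      temporal_curvature, bbox_min, span)

    # F = 1 + (r/100)·[(1-κ)·u + κ·u²/u_last], u = n·dt/300.
    m1 = (1.0 - temporal_curvature) * dt / 300.0
    m2 = temporal_curvature * dt / (300.0 * n_last)
    coeffs = np.zeros((3, 3, 3, 3))
    coeffs[0, 0, 0, 0] = 1.0
    spatial_idx = [(0, 0, 0), (1, 0, 0), (0, 1, 0), (0, 0, 1)]
    for ck, (a, b_, g) in zip(coef / 100.0, spatial_idx):
        coeffs[1, a, b_, g] = ck * m1
        coeffs[2, a, b_, g] = ck * m2
    return SpatiotemporalDriftModel(coeffs, bbox_min, bbox_max,
                                    reference_index=0)


def _null_space(A: np.ndarray) -> np.ndarray:
    _, s, vt = np.linalg.svd(A)
    rank = int(np.sum(s > 1e-12 * s.max()))
    return vt[rank:].T


def _temporal_weights(scheme: AcquisitionScheme, kappa: float
                      ) -> tuple[np.ndarray, np.ndarray]:
    """(b0 indices, w_i) with F(n_i) = 1 + r/100 · w_i at the b = 0 volumes."""
    idx = scheme.b0_indices
    dt = scheme.volume_interval
    u = idx * dt / 300.0
    u_last = (len(scheme) - 1) * dt / 300.0
    return idx, (1.0 - kappa) * u + kappa * u ** 2 / u_last


def _flatten_median_signal(coef, null, phantom, scheme, kappa,
                           bbox_min, span) -> np.ndarray:
    """Adjust the profile along the pole-constraint null space so the
    masked median of S0 · F(n) is as flat as possible over the b = 0
    volumes (the trajectory a global correction would fit)."""
    from scipy.optimize import minimize

    vox = np.argwhere(phantom.mask).astype(float)
    B = np.column_stack([np.ones(len(vox)),
                         2.0 * (vox - bbox_min) / span - 1.0])
    S0 = phantom.maps.S0[phantom.mask]
    _, w = _temporal_weights(scheme, kappa)

    ref = np.median(S0)

    def cost(alpha):
        rv = B @ (coef + null @ alpha)
        med = np.median(S0[:, None] * (1.0 + np.outer(rv, w) / 100.0), axis=0)
        signal_term = float(np.sum((med / ref - 1.0) ** 2))
        # keep the adjusted profile within the allowed magnitude family
        excess = max(0.0, float(np.max(np.abs(rv))) - 20.0)
        return signal_term + 1e3 * excess ** 2

    # The objective is piecewise (medians of a finite set): seed a simplex
    # polish from a coarse grid to avoid poor local minima.
    dim = null.shape[1]
    pts = {1: 33, 2: 17}.get(dim, 9)
    axes = [np.linspace(-8.0, 8.0, pts)] * dim
    grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, dim)
    alpha0 = min(grid, key=cost)
    res = minimize(cost, alpha0, method="Nelder-Mead",
                   options={"xatol": 1e-8, "fatol": 1e-16, "maxiter": 2000})
    best = res.x if res.fun <= cost(alpha0) else alpha0
    return coef + null @ best


def apply_drift(series: ImageSeries,
                model: SpatiotemporalDriftModel) -> ImageSeries:
    """Multiply the series by the model's drift field (inside the mask)."""
    return apply_inverse(series, model)


def sigma_for_snr(series: ImageSeries, snr: float) -> float:
    """Noise standard deviation giving the requested SNR at the masked
    median b = 0 signal."""
    idx = series.scheme.b0_indices
    ref = np.median(series.data[series.mask][:, idx])
    return float(ref) / snr


def add_noise(series: ImageSeries, sigma: float, model: str = "rician",
              seed: int = 0) -> ImageSeries:
    """Add Rician (default) or truncated Gaussian noise of sd sigma."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0:
        return series.copy_with(series.data.copy())
    rng = np.random.default_rng(seed)
    if model == "rician":
        e1 = rng.normal(0.0, sigma, series.data.shape)
        e2 = rng.normal(0.0, sigma, series.data.shape)
        noisy = np.sqrt((series.data + e1) ** 2 + e2 ** 2)
    elif model == "gaussian":
        noisy = np.clip(series.data + rng.normal(0.0, sigma, series.data.shape),
                        0.0, None)
    else:
        raise ValueError(f"unknown noise model {model!r}")
    return series.copy_with(noisy)
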