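"""Signal-drift estimation and correction.

Slow multiplicative intensity drift is monitored through the b = 0 volumes
interspersed in a scan and modeled as a second-order polynomial in the
acquisition index n:

    S(n | b_n = 0) = k0 + k1·n + k2·n²

fitted either to the whole-mask median b = 0 signal (global), per voxel
(voxelwise), or — after voxelwise normalization to the first b = 0 volume —
as a second-order polynomial in both time and space,

    S(n; x, y, z | b_n = 0) = p0(x,y,z) + p1(x,y,z)·n + p2(x,y,z)·n²

where each p_i contains all zeroth/first/second-order combinations of the
spatial coordinates, i.e. 81 coefficients in total, estimated by robust
bisquare (Tukey biweight) regression.  The correction divides every volume,
diffusion-weighted or not, by the fitted polynomial; here the divisor is
additionally normalized to 1 at a reference acquisition (the first b = 0
volume) so that corrected data keep the physical scale of the start of the
scan — IVIM estimates are invariant to this normalization.

The module also provides the acquisition-order simulation: spatiotemporally
corrected data are re-sorted into ascending-b order and the inverse
correction is applied at the new indices, producing an uncorrected series
as if it had been acquired b-ordered under the same drift.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
import numpy as np
import statsmodels.api as sm

from .containers import ImageSeries
from .scheme import AcquisitionScheme, ordered_scheme, ordering_permutation

__all__ = [
    "GlobalDriftModel",
    "VoxelwiseDriftModel",
    "SpatiotemporalDriftModel",
    "fit_global",
    "fit_voxelwise",
    "fit_spatiotemporal",
    "evaluate_field",
    "apply_correction",
    "apply_inverse",
    "simulate_ordered",
    "spatiotemporal_design",
    "N_SPATIOTEMPORAL_COEFFICIENTS",
]

logger = logging.getLogger(__name__)

#: 3 temporal orders × 27 spatial monomials (orders 0–2 per axis).
N_SPATIOTEMPORAL_COEFFICIENTS = 81

#: Tukey biweight tuning constant (95% Gaussian efficiency).
BISQUARE_TUNING = 4.685


@dataclass
class GlobalDriftModel:
    """Single temporal polynomial fitted to the whole-mask median b=0 signal."""

    k0: float
    k1: float
    k2: float
    reference_index: int = 0

    def fitted(self, n) -> np.ndarray:
        n = np.asarray(n, dtype=float)
        return self.k0 + self.k1 * n + self.k2 * n ** 2

    def to_json(self) -> str:
        return json.dumps({"kind": "global", "k": [self.k0, self.k1, self.k2],
                           "reference_index": self.reference_index})


@dataclass
class VoxelwiseDriftModel:
    """One temporal polynomial per masked voxel."""

    k0: np.ndarray
    k1: np.ndarray
    k2: np.ndarray
    mask: np.ndarray
    reference_index: int = 0

    def fitted(self, n) -> np.ndarray:
        """(X, Y, Z, len(n)) fitted values."""
        n = np.atleast_1d(np.asarray(n, dtype=float))
        return (self.k0[..., None] + self.k1[..., None] * n
                + self.k2[..., None] * n ** 2)


@dataclass
class SpatiotemporalDriftModel:
    """81-coefficient polynomial, second order in space and time.

    ``coefficients[i, a, b, g]`` multiplies n^i · X^a · Y^b · Z^g where X,
    Y, Z are voxel indices affinely normalized to [-1, 1] over the mask
    bounding box stored in ``bbox_min``/``bbox_max``.
    """

    coefficients: np.ndarray  # shape (3, 3, 3, 3)
    bbox_min: np.ndarray      # (3,) voxel-index lower corner
    bbox_max: np.ndarray      # (3,) voxel-index upper corner
    reference_index: int = 0
    converged: bool = True

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if self.coefficients.shape != (3, 3, 3, 3):
            raise ValueError("spatiotemporal model requires a (3,3,3,3) "
                             "coefficient array (81 scalars)")
        self.bbox_min = np.asarray(self.bbox_min, dtype=float)
        self.bbox_max = np.asarray(self.bbox_max, dtype=float)

    def normalized_coords(self, shape) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        axes = []
        for k in range(3):
            idx = np.arange(shape[k], dtype=float)
            span = self.bbox_max[k] - self.bbox_min[k]
            if span == 0:
                axes.append(np.zeros(shape[k]))
            else:
                axes.append(2.0 * (idx - self.bbox_min[k]) / span - 1.0)
        return np.meshgrid(*axes, indexing="ij")

    def temporal_polys(self, shape) -> np.ndarray:
        """(3, X, Y, Z) maps of p0, p1, p2 over the grid."""
        X, Y, Z = self.normalized_coords(shape)
        xp = np.stack([np.ones_like(X), X, X ** 2])
        yp = np.stack([np.ones_like(Y), Y, Y ** 2])
        zp = np.stack([np.ones_like(Z), Z, Z ** 2])
        p = np.einsum("iabg,axyz,bxyz,gxyz->ixyz",
                      self.coefficients, xp, yp, zp)
        return p

    def fitted(self, n, shape) -> np.ndarray:
        """(X, Y, Z, len(n)) fitted values over the grid."""
        n = np.atleast_1d(np.asarray(n, dtype=float))
        p = self.temporal_polys(shape)
        return (p[0][..., None] + p[1][..., None] * n
                + p[2][..., None] * n ** 2)

    def to_json(self) -> str:
        return json.dumps({
            "kind": "spatiotemporal",
            "coefficients": self.coefficients.tolist(),
            "bbox_min": self.bbox_min.tolist(),
            "bbox_max": self.bbox_max.tolist(),
            "reference_index": self.reference_index,
        })

    @classmethod
    def from_json(cls, text: str) -> "SpatiotemporalDriftModel":
        d = json.loads(text)
        return cls(np.array(d["coefficients"]), np.array(d["bbox_min"]),
                   np.array(d["bbox_max"]), int(d["reference_index"]))


def _b0_subset(series: ImageSeries) -> np.ndarray:
    idx = series.scheme.b0_indices
    if idx.size < 3:
        raise ValueError(
            f"drift fitting needs >= 3 b = 0 acquisitions, got {idx.size}"
        )
    return idx


def _fit_quadratic(n: np.ndarray, y: np.ndarray) -> np.ndarray:
    """OLS quadratic fit of y (n_obs, ...) against raw index n; returns
    coefficients (3, ...) in the raw-n basis.  The solve runs on the
    normalized variable tau = n / n_max for conditioning."""
    n_max = float(n.max()) if n.max() > 0 else 1.0
    tau = n / n_max
    A = np.vander(tau, 3, increasing=True)
    coef, *_ = np.linalg.lstsq(A, y.reshape(len(n), -1), rcond=None)
    coef = coef.reshape((3,) + y.shape[1:])
    scale = np.array([1.0, 1.0 / n_max, 1.0 / n_max ** 2])
    return coef * scale.reshape((3,) + (1,) * (y.ndim - 1))


def fit_global(series: ImageSeries) -> GlobalDriftModel:
    """Fit one temporal polynomial to the masked median b = 0 signal."""
    idx = _b0_subset(series)
    med = np.array([np.median(series.data[series.mask, i]) for i in idx])
    if np.any(med <= 0):
        raise ValueError("nonpositive median b = 0 signal")
    k = _fit_quadratic(idx.astype(float), med[:, None])[:, 0]
    model = GlobalDriftModel(float(k[0]), float(k[1]), float(k[2]),
                             reference_index=int(idx[0]))
    if np.any(model.fitted(np.arange(len(series.scheme))) <= 0):
        raise ValueError("global drift fit is nonpositive within the scan")
    return model


def fit_voxelwise(series: ImageSeries) -> VoxelwiseDriftModel:
    """Fit an independent temporal polynomial per masked voxel.

    Voxels whose fitted polynomial is nonpositive anywhere in the scan are
    dropped from the model mask with a logged warning.
    """
    idx = _b0_subset(series)
    mask = series.mask.copy()
    y = series.data[mask][:, idx].T  # (n_b0, n_voxels)
    coef = _fit_quadratic(idx.astype(float), y)  # (3, n_voxels)

    shape = series.shape
    k0 = np.zeros(shape); k1 = np.zeros(shape); k2 = np.zeros(shape)
    k0[mask], k1[mask], k2[mask] = coef

    alln = np.arange(len(series.scheme), dtype=float)
    fitted = coef[0][:, None] + coef[1][:, None] * alln + coef[2][:, None] * alln ** 2
    bad = np.any(fitted <= 0, axis=1)
    if bad.any():
        logger.warning("voxelwise drift fit: dropping %d voxel(s) with "
                       "nonpositive fitted values", int(bad.sum()))
        flat = np.flatnonzero(mask.ravel())[bad]
        mask = mask.copy()
        mask.ravel()[flat] = False
    return VoxelwiseDriftModel(k0, k1, k2, mask, reference_index=int(idx[0]))


def spatiotemporal_design(n: np.ndarray, X: np.ndarray, Y: np.ndarray,
                          Z: np.ndarray) -> np.ndarray:
    """81-column design: all products n^i·X^a·Y^b·Z^g, orders 0–2 each.

    Column order matches ``SpatiotemporalDriftModel.coefficients`` raveled
    C-style over (i, a, b, g).
    """
    cols = []
    for i in range(3):
        for a in range(3):
            for bb in range(3):
                for g in range(3):
                    cols.append((n ** i) * (X ** a) * (Y ** bb) * (Z ** g))
    return np.column_stack(cols)


def fit_spatiotemporal(series: ImageSeries, max_iter: int = 50,
                       tol: float = 1e-8) -> SpatiotemporalDriftModel:
    """Fit the 81-coefficient spatiotemporal polynomial by bisquare regression.

    Every masked b = 0 volume is first divided voxelwise by the first b = 0
    volume to remove the anatomical signal distribution; the normalized
    values are then regressed on the 81-term design with iteratively
    reweighted least squares under the Tukey biweight loss (tuning constant
    4.685, MAD residual scale).  Noiseless in-family data short-circuit to
    the exact least-squares solution.
    """
    idx = _b0_subset(series)
    mask = np.asarray(series.mask, dtype=bool)
    nvox = int(mask.sum())
    if nvox == 0:
        raise ValueError("empty mask")
    if nvox * idx.size < 5 * N_SPATIOTEMPORAL_COEFFICIENTS:
        raise ValueError(
            f"too few b = 0 samples ({nvox * idx.size}) for "
            f"{N_SPATIOTEMPORAL_COEFFICIENTS} coefficients; need >= "
            f"{5 * N_SPATIOTEMPORAL_COEFFICIENTS}"
        )

    ref_vol = series.data[..., idx[0]]
    valid = mask & (ref_vol > 0)
    if valid.sum() < mask.sum():
        logger.warning("spatiotemporal fit: %d masked voxel(s) with "
                       "nonpositive reference signal excluded",
                       int(mask.sum() - valid.sum()))

    # Normalized response: one row per (b0 volume, voxel).
    y = (series.data[valid][:, idx] / ref_vol[valid][:, None]).T.ravel()

    # Normalized coordinates over the mask bounding box.
    ijk = np.argwhere(mask)
    bbox_min = ijk.min(axis=0).astype(float)
    bbox_max = ijk.max(axis=0).astype(float)
    span = np.where(bbox_max > bbox_min, bbox_max - bbox_min, 1.0)
    vox = np.argwhere(valid).astype(float)
    XYZ = 2.0 * (vox - bbox_min) / span - 1.0

    n_max = float(idx.max()) if idx.max() > 0 else 1.0
    tau = (idx.astype(float) / n_max)[:, None].repeat(len(vox), 1).ravel()
    Xc = np.tile(XYZ[:, 0], idx.size)
    Yc = np.tile(XYZ[:, 1], idx.size)
    Zc = np.tile(XYZ[:, 2], idx.size)
    A = spatiotemporal_design(tau, Xc, Yc, Zc)

    beta, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ beta
    converged = True
    # IRLS is pointless (and its MAD scale degenerate) on an exact fit.
    if np.max(np.abs(resid)) > 1e-9:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rlm = sm.RLM(y, A, M=sm.robust.norms.TukeyBiweight(c=BISQUARE_TUNING))
            res = rlm.fit(maxiter=max_iter, tol=tol, scale_est="mad")
        beta = res.params
        converged = bool(getattr(res, "converged", True))
        if not converged:
            logger.warning("spatiotemporal IRLS did not converge in %d "
                           "iterations; returning last iterate", max_iter)

    coeffs = beta.reshape(3, 3, 3, 3)
    # Back to the raw acquisition-index basis.
    coeffs = coeffs * np.array([1.0, 1.0 / n_max, 1.0 / n_max ** 2]
                               ).reshape(3, 1, 1, 1)
    return SpatiotemporalDriftModel(coeffs, bbox_min, bbox_max,
                                    reference_index=int(idx[0]),
                                    converged=converged)


DriftModel = GlobalDriftModel | VoxelwiseDriftModel | SpatiotemporalDriftModel


def evaluate_field(model: DriftModel, scheme: AcquisitionScheme,
                   shape: tuple[int, int, int],
                   mask: np.ndarray | None = None) -> np.ndarray:
    """Dimensionless correction field over the grid and scheme.

    field(x, y, z, n) = fitted(n; x, y, z) / fitted(reference; x, y, z),
    equal to 1 at the reference acquisition.  Outside the mask (or, for the
    voxelwise model, outside its valid-fit mask) the field is 1.  Masked
    voxels with a nonpositive fitted value are set to 1 and reported.
    """
    n = np.arange(len(scheme), dtype=float)
    if isinstance(model, GlobalDriftModel):
        ratio = model.fitted(n) / model.fitted(model.reference_index)
        field = np.broadcast_to(ratio, shape + (len(scheme),)).copy()
        if mask is None:
            return field
        out = np.ones(shape + (len(scheme),))
        out[mask] = field[mask]
        return out

    if isinstance(model, VoxelwiseDriftModel):
        fit = model.fitted(n)
        ref = model.fitted(float(model.reference_index))[..., 0]
        domain = model.mask if mask is None else (mask & model.mask)
    elif isinstance(model, SpatiotemporalDriftModel):
        fit = model.fitted(n, shape)
        ref = model.fitted(float(model.reference_index), shape)[..., 0]
        domain = np.ones(shape, dtype=bool) if mask is None else mask
    else:
        raise TypeError(f"unsupported drift model {type(model).__name__}")

    field = np.ones(shape + (len(scheme),))
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = fit / ref[..., None]
    good = domain & (ref > 0) & np.all(fit > 0, axis=-1)
    bad = int(domain.sum() - good.sum())
    if bad:
        logger.warning("drift field: %d voxel(s) with nonpositive fitted "
                       "values left uncorrected", bad)
    field[good] = ratio[good]
    return field


def apply_correction(series: ImageSeries, model: DriftModel) -> ImageSeries:
    """Divide the series by the normalized drift field (all b-values)."""
    field = evaluate_field(model, series.scheme, series.shape, series.mask)
    if np.any(field <= 0):
        raise ValueError("nonpositive correction field")
    return series.copy_with(series.data / field)


def apply_inverse(series: ImageSeries, model: DriftModel) -> ImageSeries:
    """Multiply the series by the drift field (re-impose the drift)."""
    field = evaluate_field(model, series.scheme, series.shape, series.mask)
    return series.copy_with(series.data * field)


def simulate_ordered(corrected: ImageSeries,
                     model: SpatiotemporalDriftModel) -> ImageSeries:
    """Simulate an ascending-b acquisition under the estimated drift.

    The drift-corrected volumes are permuted into ascending-b order (with
    encoding directions in direct succession) and the inverse correction is
    applied at the new acquisition indices, yielding an uncorrected series
    as if the same drift had acted on a b-ordered protocol.
    """
    perm = ordering_permutation(corrected.scheme)
    new_scheme = ordered_scheme(corrected.scheme)
    reordered = corrected.copy_with(corrected.data[..., perm], new_scheme)
    return apply_inverse(reordered, model)
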