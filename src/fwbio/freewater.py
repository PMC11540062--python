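"""Bi-tensor free-water modelling on single-shell diffusion MRI.

Model
-----
Each voxel's normalised signal (attenuation) in direction g at b-value b is

    A(b, g) = (1 - f) * exp(-b * g' D g) + f * exp(-b * d_w)

where ``f`` is the free-water volume fraction, ``D`` the tissue diffusion
tensor and ``d_w`` the diffusivity of free water (default 3.0e-3 mm^2/s,
the literature value at body temperature).  With a single non-zero shell
the model is ill-posed for isotropic tissue (a continuum of (f, D) pairs
fits exactly), so the fit constrains tissue eigenvalues to a physiological
band, bounds f in [0, 1], and flags near-isotropic voxels as degenerate
rather than reporting an arbitrary point on the ridge.

Fitting
-------
Per voxel, bounded nonlinear least squares on (f, L) where ``D = L L'``
and L is a lower-triangular Cholesky factor, which keeps D positive
semidefinite by construction.  Eigenvalue bounds are enforced by spectral
projection after the fit (``clipped`` flag when active).  Initialisation
comes from the conventional tensor fit: f0 by attenuation interpolation
between a typical-tissue and the free-water mean diffusivity, D0 from a
log-linear refit of the f0-corrected attenuations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.optimize import least_squares

from .dti import (
    DWIVolume,
    design_matrix,
    fit_dti_loglinear,
    fractional_anisotropy,
    tensor_from_lower,
)
from .protocol import AcquisitionProtocol

__all__ = ["FitOptions", "FWMaps", "fit_bitensor_voxel", "compute_fw_maps"]


@dataclass(frozen=True)
class FitOptions:
    """Constants governing the bi-tensor fit.

    d_water : free-water diffusivity, mm^2/s
    eig_bounds : allowed tissue-tensor eigenvalue band, mm^2/s
    f_bounds : allowed free-water fraction range
    md_tissue_init : typical tissue mean diffusivity used by the f0
        initialisation heuristic, mm^2/s
    regularization : "none" (per-voxel fit) or "smooth_init" (Gaussian
        smoothing, sigma = 1 voxel, of the f0 map before fitting)
    fa_degenerate_threshold : voxels with conventional FA below this are
        flagged degenerate and keep their initialisation values
    """

    d_water: float = 3.0e-3
    eig_bounds: tuple = (0.1e-3, 2.5e-3)
    f_bounds: tuple = (0.0, 1.0)
    md_tissue_init: float = 0.6e-3
    max_iter: int = 200
    tol: float = 1e-10
    regularization: str = "none"
    fa_degenerate_threshold: float = 0.05

    def __post_init__(self) -> None:
        lo, hi = self.eig_bounds
        if not (0 < lo < hi < self.d_water):
            raise ValueError("need 0 < eig_min < eig_max < d_water")
        flo, fhi = self.f_bounds
        if not (0.0 <= flo < fhi <= 1.0):
            raise ValueError("f_bounds must be within [0, 1]")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.regularization not in ("none", "smooth_init"):
            raise ValueError("regularization must be 'none' or 'smooth_init'")


@dataclass
class FWMaps:
    """Voxelwise outputs of the free-water fit."""

    fw: np.ndarray
    tissue_tensors: np.ndarray  # (X, Y, Z, 3, 3)
    fa_fwcorr: np.ndarray
    fa_conv: np.ndarray
    s0: np.ndarray
    flags: dict  # name -> boolean map: converged, degenerate_isotropic, clipped
    mask: np.ndarray
    affine: np.ndarray | None = None


def _project_eigenvalues(D: np.ndarray, bounds: tuple) -> tuple:
    """Clip the spectrum of a symmetric 3x3 tensor into ``bounds``."""
    lam, V = np.linalg.eigh(D)
    lam_c = np.clip(lam, bounds[0], bounds[1])
    clipped = bool(np.any(np.abs(lam_c - lam) > 1e-15))
    return (V * lam_c) @ V.T, lam_c, clipped


def _cholesky_from_tensor(D: np.ndarray, bounds: tuple) -> np.ndarray:
    Dp, _, _ = _project_eigenvalues(D, bounds)
    return np.linalg.cholesky(Dp)


def fw_init_fraction(md_conv: np.ndarray, b: float, opts: FitOptions) -> np.ndarray:
    """Attenuation-interpolation heuristic for the initial FW fraction.

    Places exp(-b*MD_conv) between the attenuation of typical tissue
    (md_tissue_init) and of free water, clamped to [0.01, 0.99].
    """
    a = np.exp(-b * np.asarray(md_conv, dtype=float))
    a_t = np.exp(-b * opts.md_tissue_init)
    a_w = np.exp(-b * opts.d_water)
    f0 = (a - a_t) / (a_w - a_t)
    return np.clip(f0, 0.01, 0.99)


def _residuals_and_jac(x, b, g, attn, e_w):
    """Residuals m(x) - attn and the analytic Jacobian.

    x = [f, L00, L10, L11, L20, L21, L22] (row-major lower triangle).
    """
    f = x[0]
    L = np.zeros((3, 3))
    L[0, 0], L[1, 0], L[1, 1], L[2, 0], L[2, 1], L[2, 2] = x[1:]
    Ltg = g @ L  # (V, 3) rows are (L' g_k)'
    q = np.einsum("ij,ij->i", Ltg, Ltg)  # g' L L' g
    e_t = np.exp(-b * q)
    model = (1.0 - f) * e_t + f * e_w
    r = model - attn

    J = np.empty((b.shape[0], 7))
    J[:, 0] = e_w - e_t
    dm_dq = -(1.0 - f) * b * e_t  # (V,)
    # dq/dL_ab = 2 * g_a * (L'g)_b for lower-triangular entries
    J[:, 1] = dm_dq * 2.0 * g[:, 0] * Ltg[:, 0]  # L00
    J[:, 2] = dm_dq * 2.0 * g[:, 1] * Ltg[:, 0]  # L10
    J[:, 3] = dm_dq * 2.0 * g[:, 1] * Ltg[:, 1]  # L11
    J[:, 4] = dm_dq * 2.0 * g[:, 2] * Ltg[:, 0]  # L20
    J[:, 5] = dm_dq * 2.0 * g[:, 2] * Ltg[:, 1]  # L21
    J[:, 6] = dm_dq * 2.0 * g[:, 2] * Ltg[:, 2]  # L22
    return r, J


def fit_bitensor_voxel(
    signals: np.ndarray,
    protocol: AcquisitionProtocol,
    init: tuple,
    opts: FitOptions = FitOptions(),
) -> tuple:
    """Fit (f, D) for one voxel by bounded least squares on attenuations.

    Parameters
    ----------
    signals : per-volume signal values (length = protocol volumes)
    init : (f0, D0) starting point; D0 is a symmetric 3x3 tensor
    Returns ``(f, D, diagnostics)``.  Diagnostics record convergence, the
    final cost, iteration count and whether the eigenvalue projection or
    the f bounds were active (``clipped``).
    """
    signals = np.asarray(signals, dtype=float)
    if not np.all(np.isfinite(signals)):
        raise ValueError("non-finite signal values")
    b0 = signals[protocol.b0_mask].mean()
    if b0 <= 0:
        raise ValueError("mean b=0 signal must be positive")
    attn = np.clip(signals / b0, 1e-6, None)

    # near-isotropic signals: the single-shell problem is degenerate along
    # the (f, MD) ridge — report the initialisation heuristic instead of an
    # arbitrary ridge point
    X = design_matrix(protocol)
    beta = np.linalg.pinv(X) @ np.log(attn)
    lam_conv = np.linalg.eigvalsh(tensor_from_lower(beta[1:]))
    if fractional_anisotropy(lam_conv) < opts.fa_degenerate_threshold:
        b_shell = float(np.mean(protocol.bvals[protocol.bvals > 0]))
        md_conv = float(np.mean(lam_conv))
        f_deg = float(fw_init_fraction(md_conv, b_shell, opts))
        lam_iso = float(np.clip(md_conv, *opts.eig_bounds))
        diagnostics = {"converged": True, "cost": np.nan, "n_iter": 0,
                       "clipped": False, "status": 0,
                       "degenerate_isotropic": True}
        return f_deg, np.eye(3) * lam_iso, diagnostics

    f0, D0 = init
    flo, fhi = opts.f_bounds
    f0 = float(np.clip(f0, max(flo, 1e-3), min(fhi, 1.0 - 1e-3)))
    L0 = _cholesky_from_tensor(np.asarray(D0, dtype=float), opts.eig_bounds)

    b = protocol.bvals
    g = protocol.bvecs
    e_w = np.exp(-b * opts.d_water)

    lmax = np.sqrt(opts.eig_bounds[1]) * 2.0
    lower = np.array([flo, 0.0, -lmax, 0.0, -lmax, -lmax, 0.0])
    upper = np.array([fhi, lmax, lmax, lmax, lmax, lmax, lmax])
    x0 = np.array([f0, L0[0, 0], L0[1, 0], L0[1, 1], L0[2, 0], L0[2, 1], L0[2, 2]])
    x0 = np.clip(x0, lower, upper)

    res = least_squares(
        lambda x: _residuals_and_jac(x, b, g, attn, e_w)[0],
        x0,
        jac=lambda x: _residuals_and_jac(x, b, g, attn, e_w)[1],
        bounds=(lower, upper),
        method="trf",
        ftol=opts.tol,
        xtol=1e-12,
        gtol=1e-12,
        max_nfev=opts.max_iter,
        x_scale=[1.0, 0.05, 0.05, 0.05, 0.05, 0.05, 0.05],
    )

    f_hat = float(res.x[0])
    L = np.zeros((3, 3))
    L[0, 0], L[1, 0], L[1, 1], L[2, 0], L[2, 1], L[2, 2] = res.x[1:]
    D_raw = L @ L.T
    D_hat, lam, eig_clipped = _project_eigenvalues(D_raw, opts.eig_bounds)
    f_clipped = f_hat <= flo + 1e-12 or f_hat >= fhi - 1e-12

    diagnostics = {
        "converged": bool(res.status > 0),
        "cost": float(res.cost),
        "n_iter": int(res.nfev),
        "clipped": bool(eig_clipped or f_clipped),
        "status": int(res.status),
        "degenerate_isotropic": False,
    }
    return f_hat, D_hat, diagnostics


def compute_fw_maps(dwi: DWIVolume, opts: FitOptions = FitOptions()) -> FWMaps:
    """Fit the bi-tensor model over every in-mask voxel of a DWI volume.

    Steps: conventional log-linear fit (for fa_conv, S0 and the
    initialisation); f0/D0 heuristics; optional Gaussian smoothing of f0;
    per-voxel bounded least squares.  Voxels whose conventional FA falls
    below ``fa_degenerate_threshold`` are flagged ``degenerate_isotropic``
    and report the initialisation values (the single-shell model cannot
    separate f from an isotropic tissue tensor there).
    """
    if not np.any(dwi.mask):
        raise ValueError("mask is empty")
    tensors_conv, s0, fa_conv = fit_dti_loglinear(dwi)

    shell = np.unique(dwi.protocol.bvals[dwi.protocol.bvals > 0])
    if shell.size != 1:
        raise ValueError("compute_fw_maps expects a single-shell protocol")
    b_shell = float(shell[0])

    shape = dwi.spatial_shape
    md_conv = np.trace(tensors_conv, axis1=-2, axis2=-1) / 3.0
    f0_map = np.zeros(shape)
    f0_map[dwi.mask] = fw_init_fraction(md_conv[dwi.mask], b_shell, opts)
    if opts.regularization == "smooth_init":
        sm = gaussian_filter(f0_map * dwi.mask, sigma=1.0)
        wt = gaussian_filter(dwi.mask.astype(float), sigma=1.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            f0_map = np.where(dwi.mask, sm / np.maximum(wt, 1e-12), 0.0)
        f0_map = np.clip(f0_map, 0.01, 0.99)

    fw = np.zeros(shape)
    tissue = np.zeros(shape + (3, 3))
    fa_fwcorr = np.zeros(shape)
    flags = {
        "converged": np.zeros(shape, dtype=bool),
        "degenerate_isotropic": np.zeros(shape, dtype=bool),
        "clipped": np.zeros(shape, dtype=bool),
    }

    e_w = np.exp(-dwi.protocol.bvals * opts.d_water)
    b0_mask = dwi.protocol.b0_mask
    X = design_matrix(dwi.protocol)
    pinv = np.linalg.pinv(X)

    for idx in np.argwhere(dwi.mask):
        i, j, k = idx
        sig = dwi.signal[i, j, k]
        b0 = sig[b0_mask].mean()
        if b0 <= 0:
            flags["degenerate_isotropic"][i, j, k] = True
            continue
        f0 = float(f0_map[i, j, k])
        attn = np.clip(sig / b0, 1e-6, None)
        # initial tissue tensor: log-linear refit of the f0-corrected signal
        attn_t = np.clip((attn - f0 * e_w) / (1.0 - f0), 1e-6, None)
        beta = pinv @ np.log(attn_t)
        D0, _, _ = _project_eigenvalues(tensor_from_lower(beta[1:]), opts.eig_bounds)

        if fa_conv[i, j, k] < opts.fa_degenerate_threshold:
            # near-isotropic: the single-shell fit is degenerate; keep the
            # initialisation heuristic
            fw[i, j, k] = f0
            tissue[i, j, k] = D0
            fa_fwcorr[i, j, k] = fractional_anisotropy(np.linalg.eigvalsh(D0))
            flags["degenerate_isotropic"][i, j, k] = True
            continue

        f_hat, D_hat, diag = fit_bitensor_voxel(sig, dwi.protocol, (f0, D0), opts)
        fw[i, j, k] = f_hat
        tissue[i, j, k] = D_hat
        fa_fwcorr[i, j, k] = fractional_anisotropy(np.linalg.eigvalsh(D_hat))
        flags["converged"][i, j, k] = diag["converged"]
        flags["clipped"][i, j, k] = diag["clipped"]

    return FWMaps(
        fw=fw,
        tissue_tensors=tissue,
        fa_fwcorr=fa_fwcorr,
        fa_conv=fa_conv,
        s0=s0,
        flags=flags,
        mask=dwi.mask.copy(),
        affine=dwi.affine,
    )
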