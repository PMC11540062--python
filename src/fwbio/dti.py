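"""Conventional single-tensor DTI fitting (log-linear least squares).

The single diffusion tensor model predicts the signal in direction g at
b-value b as ``S = S0 * exp(-b * g' D g)`` with D a symmetric positive
3x3 tensor.  Taking logs gives a linear model in (ln S0, Dxx, Dyy, Dzz,
Dxy, Dxz, Dyz), solved voxelwise by ordinary least squares.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .protocol import AcquisitionProtocol

__all__ = [
    "DWIVolume",
    "design_matrix",
    "fit_dti_loglinear",
    "fractional_anisotropy",
    "tensor_from_lower",
    "lower_from_tensor",
]

# ordering of the 6 unique tensor elements in the linear design
_TENSOR_ORDER = ("xx", "yy", "zz", "xy", "xz", "yz")


@dataclass
class DWIVolume:
    """4D diffusion-weighted signal plus acquisition metadata.

    signal : (X, Y, Z, V) non-negative array, one 3D volume per protocol row
    protocol : the acquisition table
    mask : (X, Y, Z) boolean brain mask
    voxel_size : voxel edge lengths in mm
    affine : voxel-to-world matrix used when writing NIfTI
    """

    signal: np.ndarray
    protocol: AcquisitionProtocol
    mask: np.ndarray
    voxel_size: tuple = (2.0, 2.0, 2.0)
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 4:
            raise ValueError("signal must be 4D (x, y, z, volume)")
        if self.signal.shape[-1] != self.protocol.n_volumes:
            raise ValueError(
                f"signal has {self.signal.shape[-1]} volumes but protocol "
                f"lists {self.protocol.n_volumes}"
            )
        if np.any(self.signal < 0):
            raise ValueError("signals must be non-negative")
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.signal.shape[:3]:
            raise ValueError("mask shape must match the spatial grid")
        if self.affine is None:
            self.affine = np.diag(list(self.voxel_size) + [1.0])

    @property
    def spatial_shape(self) -> tuple:
        return self.signal.shape[:3]


def design_matrix(protocol: AcquisitionProtocol) -> np.ndarray:
    """(V, 7) design for the log-linear fit: [1, -b*gg' terms].

    Column order: ln S0, then Dxx, Dyy, Dzz, Dxy, Dxz, Dyz with the
    off-diagonal columns carrying the usual factor 2.
    """
    b = protocol.bvals
    g = protocol.bvecs
    X = np.empty((protocol.n_volumes, 7))
    X[:, 0] = 1.0
    X[:, 1] = -b * g[:, 0] ** 2
    X[:, 2] = -b * g[:, 1] ** 2
    X[:, 3] = -b * g[:, 2] ** 2
    X[:, 4] = -2.0 * b * g[:, 0] * g[:, 1]
    X[:, 5] = -2.0 * b * g[:, 0] * g[:, 2]
    X[:, 6] = -2.0 * b * g[:, 1] * g[:, 2]
    return X


def tensor_from_lower(d6: np.ndarray) -> np.ndarray:
    """(..., 6) [Dxx,Dyy,Dzz,Dxy,Dxz,Dyz] -> (..., 3, 3) symmetric tensors."""
    d6 = np.asarray(d6, dtype=float)
    out = np.empty(d6.shape[:-1] + (3, 3))
    out[..., 0, 0] = d6[..., 0]
    out[..., 1, 1] = d6[..., 1]
    out[..., 2, 2] = d6[..., 2]
    out[..., 0, 1] = out[..., 1, 0] = d6[..., 3]
    out[..., 0, 2] = out[..., 2, 0] = d6[..., 4]
    out[..., 1, 2] = out[..., 2, 1] = d6[..., 5]
    return out


def lower_from_tensor(D: np.ndarray) -> np.ndarray:
    """(..., 3, 3) tensors -> (..., 6) unique elements."""
    D = np.asarray(D, dtype=float)
    return np.stack(
        [D[..., 0, 0], D[..., 1, 1], D[..., 2, 2],
         D[..., 0, 1], D[..., 0, 2], D[..., 1, 2]],
        axis=-1,
    )


def fractional_anisotropy(eigenvalues: np.ndarray, clamp_negative: bool = True) -> np.ndarray:
    """FA of eigenvalue triples, ``sqrt(3/2 * sum((l-MD)^2) / sum(l^2))``.

    Negative eigenvalues (numerical artefacts of noisy log-linear fits) are
    clamped to zero first.  All-zero triples return FA = 0.
    """
    lam = np.asarray(eigenvalues, dtype=float)
    if clamp_negative:
        lam = np.maximum(lam, 0.0)
    md = lam.mean(axis=-1, keepdims=True)
    num = np.sum((lam - md) ** 2, axis=-1)
    den = np.sum(lam**2, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5 * num / den)
    fa = np.where(den > 0, fa, 0.0)
    return np.clip(fa, 0.0, 1.0)


def fit_dti_loglinear(dwi: DWIVolume, signal_floor_frac: float = 1e-6):
    """Voxelwise OLS tensor fit on log-signal.

    Returns ``(tensors, s0, fa_conv)`` where ``tensors`` is (X, Y, Z, 3, 3),
    ``s0`` the fitted b=0 signal and ``fa_conv`` the conventional FA map.
    Out-of-mask voxels are zero.  All-zero in-mask voxels yield zeros.
    Signals are floored at ``signal_floor_frac`` times the voxel b=0 level
    before the log.
    """
    if dwi.protocol.n_volumes < 7:
        raise ValueError("log-linear tensor fit needs at least 7 volumes")
    if dwi.protocol.n_b0 < 1:
        raise ValueError("at least one b=0 volume is required")

    X = design_matrix(dwi.protocol)
    # one shared pseudo-inverse: same design for every voxel
    pinv = np.linalg.pinv(X)

    shape = dwi.spatial_shape
    sig = dwi.signal[dwi.mask]  # (N, V)
    b0 = sig[:, dwi.protocol.b0_mask].mean(axis=1)
    ok = b0 > 0
    floor = np.where(ok, b0 * signal_floor_frac, 1.0)[:, None]
    logs = np.log(np.maximum(sig, floor))
    beta = logs @ pinv.T  # (N, 7)

    tensors = np.zeros(shape + (3, 3))
    s0 = np.zeros(shape)
    fa = np.zeros(shape)

    d6 = beta[:, 1:]
    d6[~ok] = 0.0
    T = tensor_from_lower(d6)
    lam = np.linalg.eigvalsh(T)
    fa_vals = fractional_anisotropy(lam)
    fa_vals[~ok] = 0.0

    tensors[dwi.mask] = T
    s0[dwi.mask] = np.where(ok, np.exp(beta[:, 0]), 0.0)
    fa[dwi.mask] = fa_vals
    return tensors, s0, fa
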