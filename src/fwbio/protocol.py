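"""Diffusion acquisition protocol: b-values and gradient directions.

The default protocol mirrors a common single-shell clinical research
acquisition: five non-diffusion-weighted (b=0) volumes followed by 32
diffusion-weighted volumes at b = 1000 s/mm^2.  Because vendors rarely
publish their gradient tables, the 32 directions shipped here are a fixed
electrostatic-repulsion set (antipodally symmetric energy minimised once,
then frozen) so that every run of the package uses the identical table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["AcquisitionProtocol", "default_protocol", "ELECTROSTATIC_32"]

# Minimum-energy antipodal point set on the unit sphere (32 points).
# Minimum angular separation ~24.8 degrees.
ELECTROSTATIC_32 = np.array(
    [
        (+0.883728, -0.467970, +0.005378),
        (+0.998410, -0.042513, +0.037011),
        (+0.798214, +0.600019, +0.053206),
        (-0.389803, +0.918979, +0.059418),
        (-0.055781, -0.989197, +0.135562),
        (-0.480061, -0.860542, +0.170322),
        (-0.928779, -0.274793, +0.248714),
        (+0.645702, -0.717960, +0.260005),
        (+0.440333, +0.855438, +0.272641),
        (+0.007532, +0.952352, +0.304908),
        (-0.675895, +0.664430, +0.318901),
        (+0.908037, +0.255960, +0.331593),
        (-0.892973, +0.210715, +0.397741),
        (+0.257859, -0.867975, +0.424415),
        (+0.861453, -0.264172, +0.433719),
        (-0.678914, -0.580791, +0.449174),
        (+0.641094, +0.555230, +0.529829),
        (-0.314287, +0.773933, +0.549773),
        (-0.223452, -0.799885, +0.557004),
        (+0.560536, -0.505968, +0.655588),
        (-0.742502, -0.127447, +0.657608),
        (+0.185378, +0.718991, +0.669841),
        (-0.603552, +0.388795, +0.696105),
        (+0.714011, +0.062831, +0.697310),
        (+0.134048, -0.618423, +0.774328),
        (-0.422476, -0.450928, +0.786243),
        (+0.396423, +0.355454, +0.846464),
        (-0.169927, +0.488428, +0.855899),
        (+0.396476, -0.173254, +0.901549),
        (-0.408913, +0.042197, +0.911597),
        (-0.061948, -0.283476, +0.956976),
        (+0.052382, +0.142086, +0.988467),
    ],
    dtype=float,
)


@dataclass(frozen=True)
class AcquisitionProtocol:
    """Per-volume b-values (s/mm^2) and unit gradient directions.

    ``bvecs`` rows for b=0 volumes are zero vectors by convention; rows for
    diffusion-weighted volumes must be unit length (checked to 1e-6).
    """

    bvals: np.ndarray
    bvecs: np.ndarray

    def __post_init__(self) -> None:
        bvals = np.asarray(self.bvals, dtype=float).ravel()
        bvecs = np.asarray(self.bvecs, dtype=float).reshape(-1, 3)
        if bvals.shape[0] != bvecs.shape[0]:
            raise ValueError(
                f"bvals ({bvals.shape[0]}) and bvecs ({bvecs.shape[0]}) "
                "must have one entry per volume"
            )
        if np.any(bvals < 0):
            raise ValueError("b-values must be non-negative")
        dw = bvals > 0
        norms = np.linalg.norm(bvecs[dw], axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-6):
            bad = int(np.flatnonzero(np.abs(norms - 1.0) > 1e-6)[0])
            raise ValueError(
                f"gradient vector for diffusion-weighted volume index {bad} "
                "is not unit length"
            )
        object.__setattr__(self, "bvals", bvals)
        object.__setattr__(self, "bvecs", bvecs)

    @property
    def n_volumes(self) -> int:
        return int(self.bvals.shape[0])

    @property
    def n_b0(self) -> int:
        return int(np.sum(self.bvals == 0))

    @property
    def b0_mask(self) -> np.ndarray:
        return self.bvals == 0

    def __len__(self) -> int:  # pragma: no cover - trivial
        return self.n_volumes


def default_protocol(b: float = 1000.0, n_b0: int = 5) -> AcquisitionProtocol:
    """Single-shell protocol: ``n_b0`` b=0 volumes + 32 directions at ``b``."""
    n_dw = ELECTROSTATIC_32.shape[0]
    bvals = np.concatenate([np.zeros(n_b0), np.full(n_dw, float(b))])
    bvecs = np.vstack([np.zeros((n_b0, 3)), ELECTROSTATIC_32])
    return AcquisitionProtocol(bvals=bvals, bvecs=bvecs)
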