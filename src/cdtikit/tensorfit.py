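"""Per-voxel rank-2 diffusion tensor estimation and derived scalar maps.

The tensor is fitted log-linearly: with design matrix rows
``b [gx², gy², gz², 2 gx gy, 2 gx gz, 2 gy gz]`` the Stejskal–Tanner model
linearizes to ``-ln(S_i/S0) = B d`` for the six unique tensor components
``d = (Dxx, Dyy, Dzz, Dxy, Dxz, Dyz)``.  With exactly six encoding
directions the system is exactly determined; with more it is solved in the
least-squares sense.  Noise occasionally produces negative eigenvalues
(the tensor should be positive definite); these are repaired from in-plane
neighbours before FA and MD are computed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import (
    DimensionError,
    DWISeries,
    GradientScheme,
    InvalidParameterError,
    ScalarMap,
)

#: Component order of the packed tensor representation.
TENSOR_COMPONENTS = ("Dxx", "Dyy", "Dzz", "Dxy", "Dxz", "Dyz")

_LOG_FLOOR = 1e-6  # S_i clipped below at this fraction of S0 before the log


@dataclass
class DiffusionTensorField:
    """Packed six-component tensor field with validity mask and residuals.

    ``components`` is ``(slice, row, col, 6)`` ordered as
    :data:`TENSOR_COMPONENTS`, in mm²/s.
    """

    components: np.ndarray
    mask: np.ndarray
    residual: np.ndarray

    def as_matrices(self) -> np.ndarray:
        """Expand to symmetric ``(..., 3, 3)`` matrices."""
        d = self.components
        out = np.empty(d.shape[:-1] + (3, 3))
        out[..., 0, 0] = d[..., 0]
        out[..., 1, 1] = d[..., 1]
        out[..., 2, 2] = d[..., 2]
        out[..., 0, 1] = out[..., 1, 0] = d[..., 3]
        out[..., 0, 2] = out[..., 2, 0] = d[..., 4]
        out[..., 1, 2] = out[..., 2, 1] = d[..., 5]
        return out

    @classmethod
    def from_matrices(
        cls, tensors: np.ndarray, mask: np.ndarray, residual: np.ndarray | None = None
    ) -> "DiffusionTensorField":
        comp = np.stack(
            [
                tensors[..., 0, 0],
                tensors[..., 1, 1],
                tensors[..., 2, 2],
                tensors[..., 0, 1],
                tensors[..., 0, 2],
                tensors[..., 1, 2],
            ],
            axis=-1,
        )
        if residual is None:
            residual = np.zeros(mask.shape)
        return cls(components=comp, mask=np.asarray(mask, bool), residual=residual)


@dataclass
class EigenSystemField:
    """Sorted per-voxel eigensystem of a tensor field.

    ``eigenvalues`` is ``(slice, row, col, 3)`` descending;
    ``eigenvectors[..., :, k]`` is the unit eigenvector of ``eigenvalues
    [..., k]``.  ``repaired`` flags eigenvalues replaced by the
    negative-eigenvalue repair pass.
    """

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    mask: np.ndarray
    repaired: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.repaired is None:
            self.repaired = np.zeros(self.eigenvalues.shape, dtype=bool)


def default_s0_floor(series: DWISeries, fraction: float = 0.05) -> float:
    """Mask threshold: ``fraction`` of the robust (99th percentile) S0 max."""
    s0 = series.intensities[..., 0, :]
    robust_max = np.percentile(s0, 99.0)
    return float(fraction * robust_max)


def fit_tensor_loglinear(
    averaged: DWISeries,
    scheme: GradientScheme | None = None,
    s0_floor: float | None = None,
) -> DiffusionTensorField:
    """Log-linear tensor fit of an averaged (single-repetition) series.

    Voxels with ``S0 < s0_floor`` are masked out; diffusion-weighted
    intensities are clipped below at ``1e-6 S0`` before the logarithm.
    The per-voxel fit residual is the RMS misfit of ``-ln(S_i/S0)`` (zero,
    to machine precision, for noiseless six-direction data).
    """
    if averaged.n_repetitions != 1:
        raise DimensionError("fit expects an averaged series (1 repetition)")
    scheme = scheme or averaged.scheme
    if s0_floor is None:
        s0_floor = default_s0_floor(averaged)
    if s0_floor <= 0:
        raise InvalidParameterError("s0_floor must be positive")

    design = scheme.design_matrix()  # (n_dir, 6), includes the b-value
    arr = averaged.intensities[..., 0]  # (S, R, C, channels)
    s0 = arr[..., 0]
    dwi = arr[..., 1:]
    mask = s0 >= s0_floor

    shape = s0.shape
    comp = np.zeros(shape + (6,))
    residual = np.zeros(shape)
    if mask.any():
        s0_m = s0[mask][:, None]
        sig = np.maximum(dwi[mask], _LOG_FLOOR * s0_m)
        y = -np.log(sig / s0_m)  # (n_vox, n_dir)
        sol, *_ = np.linalg.lstsq(design, y.T, rcond=None)
        comp[mask] = sol.T
        fit = y - (design @ sol).T
        residual[mask] = np.sqrt(np.mean(fit**2, axis=1))
    return DiffusionTensorField(components=comp, mask=mask, residual=residual)


def eigendecompose(field: DiffusionTensorField) -> EigenSystemField:
    """Symmetric eigendecomposition, eigenvalues sorted descending.

    Eigenvector signs are fixed deterministically (largest-magnitude
    component made positive).  Voxels with non-finite tensor components are
    dropped from the mask.
    """
    tensors = field.as_matrices()
    finite = np.isfinite(tensors).all(axis=(-2, -1))
    mask = field.mask & finite
    evals = np.zeros(mask.shape + (3,))
    evecs = np.broadcast_to(np.eye(3), mask.shape + (3, 3)).copy()
    if mask.any():
        w, v = np.linalg.eigh(tensors[mask])  # ascending
        w = w[:, ::-1]
        v = v[:, :, ::-1]
        # sign convention: largest-|component| of each eigenvector positive
        idx = np.argmax(np.abs(v), axis=1, keepdims=True)
        signs = np.sign(np.take_along_axis(v, idx, axis=1))
        signs[signs == 0] = 1.0
        v = v * signs
        evals[mask] = w
        evecs[mask] = v
    return EigenSystemField(eigenvalues=evals, eigenvectors=evecs, mask=mask)


_NEIGHBOURS_8 = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)]


def repair_negative_eigenvalues(eig: EigenSystemField) -> EigenSystemField:
    """Replace negative eigenvalues from in-plane 8-connected neighbours.

    Single pass: each negative eigenvalue of rank k is set to the mean of
    the rank-k eigenvalues over the masked 8-neighbours (same slice) whose
    own rank-k value is non-negative, or to 0 if no such neighbour exists.
    Eigenvectors and non-negative eigenvalues are untouched.  Cross-slice
    neighbours are excluded (slices are far apart along the long axis).
    """
    evals = eig.eigenvalues.copy()
    repaired = eig.repaired.copy()
    n_s, n_r, n_c, _ = evals.shape
    negative = (eig.eigenvalues < 0) & eig.mask[..., None]
    for s, r, c, k in zip(*np.nonzero(negative)):
        donors = []
        for dr, dc in _NEIGHBOURS_8:
            rr, cc = r + dr, c + dc
            if 0 <= rr < n_r and 0 <= cc < n_c and eig.mask[s, rr, cc]:
                val = eig.eigenvalues[s, rr, cc, k]
                if val >= 0:
                    donors.append(val)
        evals[s, r, c, k] = float(np.mean(donors)) if donors else 0.0
        repaired[s, r, c, k] = True
    return EigenSystemField(
        eigenvalues=evals,
        eigenvectors=eig.eigenvectors,
        mask=eig.mask,
        repaired=repaired,
    )


def compute_md(eig: EigenSystemField) -> ScalarMap:
    """Mean diffusivity, (λ1 + λ2 + λ3)/3 — the tensor's trace/3."""
    md = eig.eigenvalues.mean(axis=-1)
    md = np.where(eig.mask, md, np.nan)
    return ScalarMap(values=md, mask=eig.mask, kind="MD")


def compute_fa(eig: EigenSystemField) -> ScalarMap:
    """Fractional anisotropy in [0, 1].

    FA = sqrt(3/2) ||λ - mean(λ)|| / ||λ||, by convention 0 where all
    eigenvalues vanish; clipped to [0, 1] against floating-point overshoot.
    """
    lam = eig.eigenvalues
    mean = lam.mean(axis=-1, keepdims=True)
    num = np.sqrt(np.sum((lam - mean) ** 2, axis=-1))
    den = np.sqrt(np.sum(lam**2, axis=-1))
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5) * num / den
    fa = np.where(den > 0, fa, 0.0)
    fa = np.clip(fa, 0.0, 1.0)
    fa = np.where(eig.mask, fa, np.nan)
    return ScalarMap(values=fa, mask=eig.mask, kind="FA")
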