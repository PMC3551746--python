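"""Synthetic left-ventricle cDTI phantom with known ground truth.

The phantom is an annular short-axis LV: per slice, a circular cavity of
radius ``endo_radius`` inside an epicardial disk of radius ``epi_radius``.
Within the wall, myocyte orientation follows a helix whose angle ramps
linearly with transmural depth from ``ha_endo`` (right-handed, positive) at
the endocardium to ``ha_epi`` (left-handed, negative) at the epicardium.
Each voxel's diffusion tensor is axially symmetric (prolate) with the
prescribed FA and MD, its principal axis along the local myocyte direction.

Diffusion-weighted intensities follow the Stejskal–Tanner attenuation
``S_i = S0 exp(-b g^T D g)``; each acquisition repetition receives an
independent integer breath-hold translation, an occasional signal-dropout
band (a corrupted frame), and Rician noise — the defects the preprocessing
stage must undo.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cardioframe import LVGeometryModel, _frame_fields, transmural_depth
from .core import (
    DWISeries,
    GeometryError,
    GradientScheme,
    InvalidParameterError,
    default_scheme,
)

__all__ = [
    "PhantomConfig",
    "PhantomTruth",
    "eigenvalues_from_fa_md",
    "build_truth",
    "simulate_dwi",
    "add_rician_noise",
    "generate_study",
]


@dataclass(frozen=True)
class PhantomConfig:
    """Acquisition and ground-truth parameters of the synthetic study.

    Defaults emulate the emulated patient protocol: 3 short-axis slices at
    2.7 mm in-plane resolution, b = 350 s/mm² with 6 encoding directions,
    10 repetitions per slice/direction, a hypertrophied 16 mm wall with a
    small end-systolic cavity, FA 0.613, MD 0.750e-3 mm²/s, a helix ramp
    from +38.9° (endo) to -34.3° (epi), and SNR ≈ 20 Rician noise.
    """

    grid_size: int = 48
    n_slices: int = 3
    pixel_spacing: float = 2.7          # mm
    endo_radius: float = 11.0           # mm
    epi_radius: float = 27.0            # mm
    ha_endo: float = 38.9               # degrees
    ha_epi: float = -34.3               # degrees
    target_fa: float = 0.613
    target_md: float = 0.750e-3         # mm^2/s
    s0: float = 1000.0
    noise_sigma: float = 50.0           # same units as s0 (SNR ~ 20)
    n_repetitions: int = 10
    shift_sd: float = 0.3               # pixels (~0.8 mm breath-hold residual)
    corrupt_prob: float = 0.05
    rv_azimuth: float = 180.0           # degrees; septum toward -col
    b_value: float = 350.0              # s/mm^2
    slice_gap: float = 4.0              # mm (8 mm slices + 4 mm gap -> 12 mm pitch)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.endo_radius < self.epi_radius:
            raise InvalidParameterError("need 0 < endo_radius < epi_radius")
        if not 0 <= self.target_fa < 1:
            raise InvalidParameterError("target_fa must be in [0, 1)")
        if self.target_md <= 0:
            raise InvalidParameterError("target_md must be positive")
        if self.n_repetitions < 1:
            raise InvalidParameterError("n_repetitions must be >= 1")
        if not 0 <= self.corrupt_prob <= 1:
            raise InvalidParameterError("corrupt_prob must be in [0, 1]")
        if self.noise_sigma < 0:
            raise InvalidParameterError("noise_sigma must be non-negative")

    @property
    def slice_positions(self) -> np.ndarray:
        pitch = 8.0 + self.slice_gap
        return np.arange(self.n_slices) * pitch


@dataclass
class PhantomTruth:
    """Ground truth of a phantom study.

    ``tensor_field`` is ``(slice, row, col, 3, 3)`` in mm²/s; ``e1_field``
    the per-voxel principal direction; ``ha/fa/md_truth`` scalar maps (NaN
    outside the myocardium); ``geometry`` the generating LV model.
    """

    tensor_field: np.ndarray
    e1_field: np.ndarray
    ha_truth: np.ndarray
    fa_truth: np.ndarray
    md_truth: np.ndarray
    depth: np.ndarray
    geometry: LVGeometryModel
    config: PhantomConfig
    shifts: np.ndarray = field(default=None)            # type: ignore[assignment]
    corrupted: np.ndarray = field(default=None)         # type: ignore[assignment]

    @property
    def mask(self) -> np.ndarray:
        return self.geometry.myocardium_mask


def eigenvalues_from_fa_md(fa: float, md: float) -> tuple[float, float, float]:
    """Axially symmetric (prolate) eigenvalues realizing a given FA and MD.

    Solves the standard FA/MD definitions for λ1 >= λ2 = λ3 >= 0:
    with δ = FA / sqrt(3 - 2 FA²), λ1 = MD (1 + 2δ) and λ2 = λ3 = MD (1 - δ).
    Recomputing FA and MD from the returned triple reproduces the inputs.
    """
    if not 0 <= fa < 1:
        raise InvalidParameterError(f"fa must be in [0, 1), got {fa}")
    if md <= 0:
        raise InvalidParameterError(f"md must be positive, got {md}")
    delta = fa / np.sqrt(3.0 - 2.0 * fa**2)
    lam1 = md * (1.0 + 2.0 * delta)
    lam23 = md * (1.0 - delta)
    return float(lam1), float(lam23), float(lam23)


def build_geometry(config: PhantomConfig) -> LVGeometryModel:
    """Annular LV geometry on the configured voxel grid."""
    n = config.grid_size
    center = (n - 1) / 2.0
    rows, cols = np.mgrid[0:n, 0:n]
    radius_mm = np.hypot(rows - center, cols - center) * config.pixel_spacing
    cavity = radius_mm < config.endo_radius
    epi = radius_mm <= config.epi_radius
    if not (epi & ~cavity).any():
        raise GeometryError("annulus too thin for the grid: empty myocardium")
    cavity = np.repeat(cavity[None], config.n_slices, axis=0)
    epi = np.repeat(epi[None], config.n_slices, axis=0)
    return LVGeometryModel(
        cavity_mask=cavity,
        epi_mask=epi,
        rv_azimuth=config.rv_azimuth,
        pixel_spacing=config.pixel_spacing,
        slice_positions=config.slice_positions,
        centroids=np.full((config.n_slices, 2), center),
    )


def build_truth(config: PhantomConfig) -> PhantomTruth:
    """Construct the ground-truth tensor field from the helix-angle ramp.

    Per myocardial voxel the local orthonormal frame (c_hat, l_hat, r_hat)
    is taken from the slice centroid; the principal axis is
    ``e1 = cos(HA) c_hat + sin(HA) l_hat`` with HA linear in transmural
    depth, ``e3 = r_hat`` (sheet-normal radial), ``e2 = e3 x e1``, and
    ``D = R diag(λ1, λ2, λ3) R^T`` — symmetric positive definite.
    """
    geometry = build_geometry(config)
    depth = transmural_depth(geometry)
    myo = geometry.myocardium_mask

    ha = np.where(myo, config.ha_endo + depth * (config.ha_epi - config.ha_endo), np.nan)
    c_hat, l_hat, _r = _frame_fields(geometry)
    r_hat = _r
    ha_rad = np.radians(ha)

    e1 = np.cos(ha_rad)[..., None] * c_hat + np.sin(ha_rad)[..., None] * l_hat
    e3 = r_hat
    e2 = np.cross(e3, e1)

    lam = eigenvalues_from_fa_md(config.target_fa, config.target_md)
    if config.target_fa == 0:
        # isotropic: orientation is irrelevant, avoid NaN frames at centroid
        tensor = np.zeros(myo.shape + (3, 3))
        tensor[myo] = config.target_md * np.eye(3)
    else:
        rot = np.stack([e1, e2, e3], axis=-1)  # columns e1, e2, e3
        tensor = np.einsum("...ij,j,...kj->...ik", rot, np.array(lam), rot)
        tensor = np.where(myo[..., None, None], tensor, 0.0)

    fa_truth = np.where(myo, config.target_fa, np.nan)
    md_truth = np.where(myo, config.target_md, np.nan)
    e1 = np.where(myo[..., None], e1, np.nan)
    return PhantomTruth(
        tensor_field=tensor,
        e1_field=e1,
        ha_truth=ha,
        fa_truth=fa_truth,
        md_truth=md_truth,
        depth=depth,
        geometry=geometry,
        config=config,
    )


def add_rician_noise(image: np.ndarray, sigma: float, seed: int) -> np.ndarray:
    """Magnitude of the image perturbed by complex Gaussian noise.

    output = |(x + n1) + i n2| with n1, n2 ~ Normal(0, sigma) i.i.d.;
    reduces to the identity at sigma = 0 and is non-negative everywhere.
    """
    if sigma < 0:
        raise InvalidParameterError("sigma must be non-negative")
    image = np.asarray(image, dtype=float)
    if sigma == 0:
        return np.abs(image)
    rng = np.random.default_rng(seed)
    real = image + rng.normal(0.0, sigma, image.shape)
    imag = rng.normal(0.0, sigma, image.shape)
    return np.hypot(real, imag)


def _integer_shift(image: np.ndarray, dr: int, dc: int) -> np.ndarray:
    """Translate by whole pixels with zero fill (no wrap-around)."""
    out = np.zeros_like(image)
    n_r, n_c = image.shape
    rs_src = slice(max(0, -dr), min(n_r, n_r - dr))
    cs_src = slice(max(0, -dc), min(n_c, n_c - dc))
    rs_dst = slice(max(0, dr), min(n_r, n_r + dr))
    cs_dst = slice(max(0, dc), min(n_c, n_c + dc))
    out[rs_dst, cs_dst] = image[rs_src, cs_src]
    return out


def simulate_dwi(
    truth: PhantomTruth,
    scheme: GradientScheme | None = None,
    config: PhantomConfig | None = None,
    *,
    seed: int | None = None,
) -> DWISeries:
    """Forward-simulate the multi-repetition DWI stack from the truth.

    Noiseless signal per voxel and direction g: ``S = S0 exp(-b g^T D g)``
    inside the myocardium, 0 elsewhere.  Each repetition then receives one
    integer-rounded rigid translation ~ round(Normal(0, shift_sd)) applied
    to all its frames, each frame is independently corrupted (rows zeroed
    over a band) with probability ``corrupt_prob``, and Rician noise of
    width ``noise_sigma`` is added.  Deterministic given the seed; applied
    shifts and corruption flags are stored on ``truth``.
    """
    config = config or truth.config
    scheme = scheme or default_scheme(config.b_value)
    rng = np.random.default_rng(config.seed if seed is None else seed)

    myo = truth.mask
    n_s, n_r, n_c = myo.shape
    n_ch = scheme.n_directions + 1
    g = scheme.directions
    # quadratic form b g^T D g for every voxel/direction
    bq = config.b_value * np.einsum("id,...de,ie->...i", g, np.nan_to_num(truth.tensor_field), g)
    signal = np.zeros((n_s, n_r, n_c, n_ch))
    signal[..., 0] = np.where(myo, config.s0, 0.0)
    signal[..., 1:] = np.where(myo[..., None], config.s0 * np.exp(-bq), 0.0)

    n_rep = config.n_repetitions
    shifts = np.round(rng.normal(0.0, config.shift_sd, size=(n_rep, 2))).astype(int)
    corrupted = rng.random((n_s, n_ch, n_rep)) < config.corrupt_prob
    band_starts = rng.integers(0, max(1, n_r - n_r // 4), size=(n_s, n_ch, n_rep))
    noise_seeds = rng.integers(0, 2**31 - 1, size=n_rep)

    stack = np.empty((n_s, n_r, n_c, n_ch, n_rep))
    band = max(1, n_r // 4)
    for rep in range(n_rep):
        dr, dc = shifts[rep]
        for s in range(n_s):
            for ch in range(n_ch):
                frame = _integer_shift(signal[s, :, :, ch], dr, dc)
                if corrupted[s, ch, rep]:
                    b0 = band_starts[s, ch, rep]
                    frame = frame.copy()
                    frame[b0 : b0 + band, :] = 0.0
                stack[s, :, :, ch, rep] = frame
        if config.noise_sigma > 0:
            stack[..., rep] = add_rician_noise(
                stack[..., rep], config.noise_sigma, int(noise_seeds[rep])
            )
    truth.shifts = shifts
    truth.corrupted = corrupted
    return DWISeries(
        intensities=stack,
        scheme=scheme,
        pixel_spacing=config.pixel_spacing,
        slice_positions=config.slice_positions,
    )


def generate_study(config: PhantomConfig, *, seed: int | None = None) -> tuple[DWISeries, PhantomTruth]:
    """Convenience wrapper: build the truth and simulate one acquisition."""
    truth = build_truth(config)
    series = simulate_dwi(truth, config=config, seed=seed)
    return series, truth
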