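"""Shared containers and error types for the cDTI pipeline.

Array layout conventions
------------------------
Image stacks are indexed ``(slice, row, col, channel, repetition)``.
Channel 0 is always the b = 0 reference; channels 1..N are the diffusion
encoded volumes in the order of the gradient scheme's direction list.
Scalar maps and masks are indexed ``(slice, row, col)``.

Gradient directions live in the image coordinate frame with
x = +col, y = +row, z = +slice (apex -> base).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np


class InvalidParameterError(ValueError):
    """A numeric parameter violates its documented domain."""


class InvalidSchemeError(ValueError):
    """Gradient scheme cannot support a rank-6 tensor fit."""


class GeometryError(ValueError):
    """Degenerate or empty left-ventricular geometry."""


class UnusableDataError(RuntimeError):
    """All repetitions of some (slice, channel) group were rejected."""


class PairingError(ValueError):
    """Paired studies do not share subjects or region keys."""


class FormatError(ValueError):
    """On-disk inputs are inconsistent (shape, scheme, sidecar mismatch)."""


class DimensionError(ValueError):
    """Arrays passed together do not share the expected shape."""


@dataclass(frozen=True)
class GradientScheme:
    """Diffusion sensitization and unit encoding directions.

    Parameters
    ----------
    b_value:
        Diffusion weighting in s/mm².
    directions:
        ``(n, 3)`` array of unit vectors, n >= 6.  The b = 0 reference is
        implicit (channel 0 of a :class:`DWISeries`) and not listed here.
    """

    b_value: float
    directions: np.ndarray

    def __post_init__(self) -> None:
        dirs = np.asarray(self.directions, dtype=float)
        if dirs.ndim != 2 or dirs.shape[1] != 3:
            raise InvalidSchemeError(f"directions must be (n, 3), got {dirs.shape}")
        if dirs.shape[0] < 6:
            raise InvalidSchemeError(
                f"need >= 6 encoding directions for a rank-6 design, got {dirs.shape[0]}"
            )
        norms = np.linalg.norm(dirs, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-6):
            raise InvalidSchemeError("encoding directions must have unit norm (1e-6)")
        object.__setattr__(self, "directions", dirs)
        if np.linalg.matrix_rank(self.design_matrix()) < 6:
            raise InvalidSchemeError("tensor design matrix is rank deficient")

    @property
    def n_directions(self) -> int:
        return int(self.directions.shape[0])

    def design_matrix(self) -> np.ndarray:
        """Rows ``b * [gx², gy², gz², 2 gx gy, 2 gx gz, 2 gy gz]``.

        With this matrix ``B`` the log-linear tensor model reads
        ``-ln(S_i / S0) = B @ d`` where ``d = (Dxx, Dyy, Dzz, Dxy, Dxz, Dyz)``.
        """
        g = self.directions
        return self.b_value * np.column_stack(
            [
                g[:, 0] ** 2,
                g[:, 1] ** 2,
                g[:, 2] ** 2,
                2 * g[:, 0] * g[:, 1],
                2 * g[:, 0] * g[:, 2],
                2 * g[:, 1] * g[:, 2],
            ]
        )


#: A standard dual-gradient six-direction encoding set (normalized columns
#: of the icosahedral scheme); rank-6 and rotationally well conditioned.
ICOSAHEDRAL_6 = np.array(
    [
        [1.0, 1.0, 0.0],
        [1.0, -1.0, 0.0],
        [0.0, 1.0, 1.0],
        [0.0, 1.0, -1.0],
        [1.0, 0.0, 1.0],
        [-1.0, 0.0, 1.0],
    ]
) / np.sqrt(2.0)


def default_scheme(b_value: float = 350.0) -> GradientScheme:
    """Six-direction dual-gradient scheme at the given b-value (s/mm²)."""
    return GradientScheme(b_value=b_value, directions=ICOSAHEDRAL_6.copy())


@dataclass
class DWISeries:
    """Multi-slice, multi-channel, multi-repetition diffusion-weighted stack.

    ``intensities`` has shape ``(n_slices, n_rows, n_cols, n_channels,
    n_repetitions)`` with channel 0 the b = 0 reference.  ``accepted`` flags
    individual frames ``(slice, channel, repetition)``; rejected frames are
    kept in the array but excluded from registration and averaging.
    """

    intensities: np.ndarray
    scheme: GradientScheme
    pixel_spacing: float
    slice_positions: np.ndarray
    accepted: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        arr = np.asarray(self.intensities, dtype=float)
        if arr.ndim != 5:
            raise DimensionError(
                f"intensities must be (slice, row, col, channel, rep), got {arr.shape}"
            )
        if arr.shape[3] != self.scheme.n_directions + 1:
            raise FormatError(
                f"channel count {arr.shape[3]} != 1 + {self.scheme.n_directions} directions"
            )
        if np.any(arr < 0):
            raise InvalidParameterError("intensities must be non-negative")
        self.intensities = arr
        self.slice_positions = np.asarray(self.slice_positions, dtype=float)
        if self.accepted is None:
            self.accepted = np.ones(
                (arr.shape[0], arr.shape[3], arr.shape[4]), dtype=bool
            )
        else:
            self.accepted = np.asarray(self.accepted, dtype=bool)
            if self.accepted.shape != (arr.shape[0], arr.shape[3], arr.shape[4]):
                raise DimensionError("accepted flags must be (slice, channel, rep)")

    @property
    def n_slices(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_channels(self) -> int:
        return self.intensities.shape[3]

    @property
    def n_repetitions(self) -> int:
        return self.intensities.shape[4]

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.intensities.shape[1:3]

    def copy_with(self, **changes) -> "DWISeries":
        return replace(self, **changes)


@dataclass
class ScalarMap:
    """Per-voxel scalar map with a validity mask.

    ``kind`` is one of ``{"FA", "MD", "HA"}`` with units dimensionless,
    mm²/s and degrees respectively.
    """

    values: np.ndarray
    mask: np.ndarray
    kind: str

    UNITS = {"FA": "dimensionless", "MD": "mm^2/s", "HA": "degrees"}

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.mask.shape:
            raise DimensionError("values and mask must share a shape")
        if self.kind not in self.UNITS:
            raise InvalidParameterError(f"unknown map kind {self.kind!r}")

    @property
    def units(self) -> str:
        return self.UNITS[self.kind]

    def masked_values(self) -> np.ndarray:
        return self.values[self.mask]
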