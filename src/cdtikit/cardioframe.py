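"""Left-ventricular geometric model, local frames, helix angles and labels.

The LV short-axis geometry is reduced to, per slice, an endocardial (cavity)
mask and an epicardial mask; the myocardium is their difference.  Local
cardiac coordinates at a voxel are built from the slice centroid:

* radial      ``r_hat`` — in-plane unit vector from centroid to voxel,
* longitudinal ``l_hat`` — long-axis unit vector, apex -> base (+slice),
* circumferential ``c_hat = l_hat x r_hat``,

a right-handed orthonormal triad.  The helix angle (HA) of the primary
eigenvector e1 is the angle between the short-axis plane and the projection
of e1 onto the c–l tangent plane, positive for right-handed (endocardial)
helices and negative for left-handed (epicardial) ones — Streeter's sign
convention — with 0° along the local circumferential direction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .core import DimensionError, GeometryError, ScalarMap

LAYER_NAMES = ("endocardial", "mesocardial", "epicardial")
WALL_NAMES = ("septal", "anterior", "lateral", "inferior")


@dataclass
class LVGeometryModel:
    """Per-slice LV masks plus the reference directions that orient frames.

    Attributes
    ----------
    cavity_mask, epi_mask:
        Boolean arrays ``(n_slices, rows, cols)``; the cavity mask is the
        endocardial blood pool, the epi mask the full epicardial disk
        (myocardium = epi & ~cavity).
    centroids:
        ``(n_slices, 2)`` array of (row, col) centroids of the cavity.
    rv_azimuth:
        Direction of the septum (RV insertion) from the LV centroid, in
        degrees, measured from the +col axis toward +row.
    pixel_spacing:
        In-plane pixel size, mm.
    slice_positions:
        Slice locations along the long axis, mm, ascending apex -> base.
    """

    cavity_mask: np.ndarray
    epi_mask: np.ndarray
    rv_azimuth: float
    pixel_spacing: float
    slice_positions: np.ndarray
    centroids: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.cavity_mask = np.asarray(self.cavity_mask, dtype=bool)
        self.epi_mask = np.asarray(self.epi_mask, dtype=bool)
        if self.cavity_mask.shape != self.epi_mask.shape or self.cavity_mask.ndim != 3:
            raise DimensionError("masks must be matching (slice, row, col) arrays")
        myo = self.myocardium_mask
        if not myo.reshape(myo.shape[0], -1).any(axis=1).all():
            raise GeometryError("empty myocardial mask in at least one slice")
        self.slice_positions = np.asarray(self.slice_positions, dtype=float)
        if self.centroids is None:
            cents = [ndimage.center_of_mass(self.cavity_mask[s])
                     for s in range(self.cavity_mask.shape[0])]
            self.centroids = np.asarray(cents, dtype=float)
        else:
            self.centroids = np.asarray(self.centroids, dtype=float)

    @property
    def n_slices(self) -> int:
        return self.cavity_mask.shape[0]

    @property
    def myocardium_mask(self) -> np.ndarray:
        return self.epi_mask & ~self.cavity_mask

    @property
    def long_axis(self) -> np.ndarray:
        """Unit long-axis vector, apex -> base (+slice direction)."""
        return np.array([0.0, 0.0, 1.0])


@dataclass
class RegionLabels:
    """Integer label maps partitioning the myocardium.

    ``slice_index`` is the slice number; ``wall`` indexes into
    :data:`WALL_NAMES`; ``layer`` indexes into :data:`LAYER_NAMES`.
    Voxels outside the mask carry -1.
    """

    mask: np.ndarray
    wall: np.ndarray
    layer: np.ndarray

    SLICE_NAMES = ("apical", "mid", "basal")

    def slice_name(self, s: int) -> str:
        if self.mask.shape[0] == 3:
            return self.SLICE_NAMES[s]
        return f"slice{s}"


def transmural_depth(geometry: LVGeometryModel) -> np.ndarray:
    """Normalized transmural depth d in [0, 1] over the myocardium.

    d = dist_to_endo / (dist_to_endo + dist_to_epi) from per-slice Euclidean
    distance transforms: distance to the cavity border and to the outside of
    the epicardial disk.  d = 0 at the endocardial border, 1 at the
    epicardial border, monotone along radial rays.
    """
    myo = geometry.myocardium_mask
    depth = np.full(myo.shape, np.nan)
    for s in range(geometry.n_slices):
        if not myo[s].any():
            raise GeometryError(f"empty myocardium in slice {s}")
        # distance from each voxel to the nearest cavity voxel / background voxel
        d_endo = ndimage.distance_transform_edt(~geometry.cavity_mask[s])
        d_epi = ndimage.distance_transform_edt(geometry.epi_mask[s])
        m = myo[s]
        total = d_endo[m] + d_epi[m]
        depth[s][m] = np.where(total > 0, d_endo[m] / np.maximum(total, 1e-12), 0.5)
    return depth


def local_frame(
    geometry: LVGeometryModel, voxel: tuple[int, int, int]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Circumferential, longitudinal and radial unit vectors at one voxel.

    Vectors are in (x, y, z) = (+col, +row, +slice) coordinates.
    """
    s, r, c = voxel
    cr, cc = geometry.centroids[s]
    dx, dy = c - cc, r - cr
    norm = np.hypot(dx, dy)
    if norm < 1e-12:
        raise GeometryError("radial direction undefined at the centroid")
    r_hat = np.array([dx / norm, dy / norm, 0.0])
    l_hat = geometry.long_axis
    c_hat = np.cross(l_hat, r_hat)
    return c_hat, l_hat, r_hat


def _frame_fields(geometry: LVGeometryModel) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized per-voxel (c_hat, l_hat, r_hat) over the full grid.

    Voxels at a centroid get NaN radial vectors (masked downstream).
    """
    n_s, n_r, n_c = geometry.cavity_mask.shape
    rows, cols = np.mgrid[0:n_r, 0:n_c]
    r_hat = np.full((n_s, n_r, n_c, 3), np.nan)
    for s in range(n_s):
        cr, cc = geometry.centroids[s]
        dx, dy = cols - cc, rows - cr
        norm = np.hypot(dx, dy)
        ok = norm > 1e-12
        r_hat[s, ok, 0] = dx[ok] / norm[ok]
        r_hat[s, ok, 1] = dy[ok] / norm[ok]
        r_hat[s, ok, 2] = 0.0
    l_hat = np.broadcast_to(geometry.long_axis, r_hat.shape)
    c_hat = np.cross(l_hat, r_hat)
    return c_hat, l_hat, r_hat


def helix_angle_map(eig, geometry: LVGeometryModel, *, degenerate_tol: float = 1e-12) -> ScalarMap:
    """Helix-angle map (degrees, [-90, +90]) from a repaired eigensystem.

    Per voxel: project e1 onto the tangent (c–l) plane, flip its sign so the
    circumferential component is non-negative (e1 is only defined up to
    sign), then ``HA = atan2(v·l_hat, v·c_hat)``.  Voxels whose projection
    nearly vanishes or whose leading eigenvalues are degenerate
    (λ1 − λ2 < degenerate_tol) are masked as unreliable.
    """
    if eig.eigenvalues.shape[:3] != geometry.cavity_mask.shape:
        raise DimensionError(
            f"eigensystem grid {eig.eigenvalues.shape[:3]} != geometry grid "
            f"{geometry.cavity_mask.shape}"
        )
    c_hat, l_hat, r_hat = _frame_fields(geometry)
    e1 = eig.eigenvectors[..., :, 0]
    v = e1 - np.sum(e1 * r_hat, axis=-1, keepdims=True) * r_hat
    v_c = np.sum(v * c_hat, axis=-1)
    v_l = np.sum(v * l_hat, axis=-1)
    flip = np.where(v_c < 0, -1.0, 1.0)
    v_c, v_l = v_c * flip, v_l * flip

    with np.errstate(invalid="ignore"):
        ha = np.degrees(np.arctan2(v_l, v_c))
        ha = np.where(np.isclose(v_c, 0.0, atol=1e-15), 90.0, ha)

    vnorm = np.sqrt(v_c**2 + v_l**2)
    degenerate = (eig.eigenvalues[..., 0] - eig.eigenvalues[..., 1]) < degenerate_tol
    mask = (
        geometry.myocardium_mask
        & eig.mask
        & np.isfinite(ha)
        & (vnorm >= 1e-9)
        & ~degenerate
    )
    ha = np.where(mask, ha, np.nan)
    return ScalarMap(values=ha, mask=mask, kind="HA")


def assign_layers(depth: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Transmural layer labels from depth: thirds with half-open boundaries.

    endocardial: d < 1/3; mesocardial: 1/3 <= d < 2/3; epicardial: d >= 2/3.
    Returns an int array, -1 outside the mask.
    """
    layer = np.full(depth.shape, -1, dtype=int)
    d = depth[mask]
    lab = np.where(d < 1 / 3, 0, np.where(d < 2 / 3, 1, 2))
    layer[mask] = lab
    return layer


def assign_walls(geometry: LVGeometryModel) -> np.ndarray:
    """Four 90° wall sectors anchored at the RV azimuth.

    The septal sector spans [-45°, +45°) around ``rv_azimuth``; anterior is
    the next 90° counterclockwise (viewed from base), lateral opposite the
    septum, inferior the remainder.  Returns an int array indexing
    :data:`WALL_NAMES`, -1 outside the myocardium.
    """
    myo = geometry.myocardium_mask
    n_s, n_r, n_c = myo.shape
    rows, cols = np.mgrid[0:n_r, 0:n_c]
    wall = np.full(myo.shape, -1, dtype=int)
    # +col is x; +row is y. Viewed from base with the long axis toward the
    # viewer, counterclockwise anatomical rotation is toward -row, so the
    # anterior sector sits at rv_azimuth - 90 in array-angle terms.
    sector_of = np.array([0, 3, 2, 1])  # quadrant around rv_azimuth -> wall index
    for s in range(n_s):
        cr, cc = geometry.centroids[s]
        az = np.degrees(np.arctan2(rows - cr, cols - cc))
        rel = np.mod(az - geometry.rv_azimuth + 45.0, 360.0)
        quad = np.floor_divide(rel, 90.0).astype(int) % 4
        wall[s][myo[s]] = sector_of[quad[myo[s]]]
    return wall


def build_labels(geometry: LVGeometryModel) -> RegionLabels:
    """Slice/wall/layer partition of the myocardial mask."""
    depth = transmural_depth(geometry)
    myo = geometry.myocardium_mask
    return RegionLabels(
        mask=myo,
        wall=assign_walls(geometry),
        layer=assign_layers(depth, myo),
    )
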