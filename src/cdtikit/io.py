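"""Readers and writers: NIfTI volumes, FSL-style bval/bvec sidecars,
geometry label maps with JSON metadata, YAML configs and CSV tables.

On disk, image axes are ordered ``(row, col, slice, channel, repetition)``
(the first three map to the NIfTI spatial axes); in memory the package
uses ``(slice, row, col, channel, repetition)``.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from .cardioframe import LVGeometryModel
from .core import DWISeries, FormatError, GradientScheme, ScalarMap
from .phantom import PhantomConfig

_BVEC_UNIT_TOL = 0.01  # non-unit b-vectors within 1% are normalized, else error


def _affine(pixel_spacing: float, slice_pitch: float) -> np.ndarray:
    return np.diag([pixel_spacing, pixel_spacing, slice_pitch, 1.0])


def _slice_pitch(slice_positions: np.ndarray) -> float:
    pos = np.asarray(slice_positions, dtype=float)
    return float(pos[1] - pos[0]) if pos.size > 1 else 1.0


def write_dwi(series: DWISeries, out_dir: str | Path, stem: str = "dwi") -> dict[str, Path]:
    """Write a series as 5-D NIfTI plus FSL-style ``bval``/``bvec`` sidecars."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    # (slice,row,col,ch,rep) -> (row,col,slice,ch,rep)
    data = np.moveaxis(series.intensities, 0, 2)
    img = nib.Nifti1Image(data, _affine(series.pixel_spacing, _slice_pitch(series.slice_positions)))
    nii = out_dir / f"{stem}.nii"
    nib.save(img, nii)

    bvals = np.concatenate([[0.0], np.full(series.scheme.n_directions, series.scheme.b_value)])
    bval_path = out_dir / f"{stem}.bval"
    bval_path.write_text(" ".join(f"{b:g}" for b in bvals) + "\n")

    bvecs = np.concatenate([np.zeros((1, 3)), series.scheme.directions]).T  # (3, n_ch)
    bvec_path = out_dir / f"{stem}.bvec"
    bvec_path.write_text(
        "\n".join(" ".join(f"{v:.10g}" for v in row) for row in bvecs) + "\n"
    )

    meta = {
        "pixel_spacing": series.pixel_spacing,
        "slice_positions": [float(p) for p in series.slice_positions],
    }
    meta_path = out_dir / f"{stem}.json"
    meta_path.write_text(json.dumps(meta, indent=2) + "\n")
    return {"nii": nii, "bval": bval_path, "bvec": bvec_path, "json": meta_path}


def read_dwi(
    nii_path: str | Path,
    bval_path: str | Path | None = None,
    bvec_path: str | Path | None = None,
) -> DWISeries:
    """Read a series written by :func:`write_dwi`.

    b-vectors within 1% of unit norm are renormalized; larger deviations
    raise :class:`FormatError`.  Round-trips :func:`write_dwi` exactly up
    to float precision.
    """
    nii_path = Path(nii_path)
    bval_path = Path(bval_path) if bval_path else nii_path.with_suffix(".bval")
    bvec_path = Path(bvec_path) if bvec_path else nii_path.with_suffix(".bvec")
    for p in (nii_path, bval_path, bvec_path):
        if not p.exists():
            raise FormatError(f"missing input file: {p}")

    img = nib.load(str(nii_path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim == 4:
        data = data[..., None]
    if data.ndim != 5:
        raise FormatError(f"expected a 4-D or 5-D DWI volume, got shape {data.shape}")
    data = np.moveaxis(data, 2, 0)  # -> (slice,row,col,ch,rep)

    bvals = np.loadtxt(bval_path, ndmin=1)
    bvecs = np.loadtxt(bvec_path, ndmin=2)
    if bvecs.shape[0] != 3:
        raise FormatError(f"bvec must have 3 rows, got {bvecs.shape}")
    if bvals.size != data.shape[3] or bvecs.shape[1] != data.shape[3]:
        raise FormatError(
            f"sidecar channel count ({bvals.size}) does not match volume "
            f"({data.shape[3]} channels)"
        )
    if bvals[0] != 0:
        raise FormatError("channel 0 must be the b = 0 reference")
    dirs = bvecs[:, 1:].T.copy()
    norms = np.linalg.norm(dirs, axis=1)
    if np.any(np.abs(norms - 1.0) > _BVEC_UNIT_TOL):
        raise FormatError("bvec contains non-unit directions (>1% off)")
    dirs /= norms[:, None]
    scheme = GradientScheme(b_value=float(bvals[1:].mean()), directions=dirs)

    meta_path = nii_path.with_suffix(".json")
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
        pixel_spacing = float(meta["pixel_spacing"])
        slice_positions = np.asarray(meta["slice_positions"], dtype=float)
    else:
        zooms = img.header.get_zooms()
        pixel_spacing = float(zooms[0])
        slice_positions = np.arange(data.shape[0]) * float(zooms[2])
    return DWISeries(
        intensities=data,
        scheme=scheme,
        pixel_spacing=pixel_spacing,
        slice_positions=slice_positions,
    )


def write_scalar_map(map_: ScalarMap, path: str | Path, pixel_spacing: float = 1.0,
                     slice_pitch: float = 1.0) -> Path:
    """Write one scalar map (NaN outside its mask) as 3-D NIfTI."""
    path = Path(path)
    data = np.moveaxis(np.where(map_.mask, map_.values, np.nan), 0, 2)
    nib.save(nib.Nifti1Image(data, _affine(pixel_spacing, slice_pitch)), path)
    return path


def write_geometry(geometry: LVGeometryModel, out_dir: str | Path, stem: str = "geometry") -> dict[str, Path]:
    """Write geometry as an integer label NIfTI (1 cavity, 2 myocardium)
    plus JSON metadata."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    labels = np.zeros(geometry.cavity_mask.shape, dtype=np.int16)
    labels[geometry.cavity_mask] = 1
    labels[geometry.myocardium_mask] = 2
    nii = out_dir / f"{stem}.nii"
    nib.save(
        nib.Nifti1Image(
            np.moveaxis(labels, 0, 2),
            _affine(geometry.pixel_spacing, _slice_pitch(geometry.slice_positions)),
        ),
        nii,
    )
    meta = {
        "rv_azimuth": geometry.rv_azimuth,
        "pixel_spacing": geometry.pixel_spacing,
        "slice_positions": [float(p) for p in geometry.slice_positions],
        "centroids": geometry.centroids.tolist(),
        "long_axis": geometry.long_axis.tolist(),
    }
    meta_path = out_dir / f"{stem}.json"
    meta_path.write_text(json.dumps(meta, indent=2) + "\n")
    return {"nii": nii, "json": meta_path}


def read_geometry(nii_path: str | Path, meta_path: str | Path | None = None) -> LVGeometryModel:
    """Read a geometry label map written by :func:`write_geometry`."""
    nii_path = Path(nii_path)
    meta_path = Path(meta_path) if meta_path else nii_path.with_suffix(".json")
    for p in (nii_path, meta_path):
        if not p.exists():
            raise FormatError(f"missing input file: {p}")
    labels = np.moveaxis(np.asarray(nib.load(str(nii_path)).dataobj), 2, 0)
    meta = json.loads(meta_path.read_text())
    return LVGeometryModel(
        cavity_mask=labels == 1,
        epi_mask=labels > 0,
        rv_azimuth=float(meta["rv_azimuth"]),
        pixel_spacing=float(meta["pixel_spacing"]),
        slice_positions=np.asarray(meta["slice_positions"], dtype=float),
        centroids=np.asarray(meta["centroids"], dtype=float) if "centroids" in meta else None,
    )


def save_config(config: PhantomConfig, path: str | Path) -> Path:
    """Write a phantom config as YAML."""
    import dataclasses

    path = Path(path)
    path.write_text(yaml.safe_dump(dataclasses.asdict(config), sort_keys=True))
    return path


def load_config(path: str | Path) -> PhantomConfig:
    """Read a phantom config from YAML (unknown keys rejected)."""
    data = yaml.safe_load(Path(path).read_text()) or {}
    try:
        return PhantomConfig(**data)
    except TypeError as exc:
        raise FormatError(f"bad phantom config {path}: {exc}") from exc


def export_eigensystem_csv(eig, geometry: LVGeometryModel, path: str | Path) -> Path:
    """Flat CSV export of the masked eigensystem (for external glyph tools)."""
    import pandas as pd

    idx = np.argwhere(eig.mask)
    rows = []
    for s, r, c in idx:
        lam = eig.eigenvalues[s, r, c]
        vecs = eig.eigenvectors[s, r, c]
        rows.append(
            {
                "slice": s, "row": r, "col": c,
                "lambda1": lam[0], "lambda2": lam[1], "lambda3": lam[2],
                **{
                    f"e{k + 1}{ax}": vecs[a, k]
                    for k in range(3)
                    for a, ax in enumerate("xyz")
                },
            }
        )
    path = Path(path)
    pd.DataFrame(rows).to_csv(path, index=False)
    return path
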