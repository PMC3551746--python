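"""End-to-end workflows: single-study analysis and paired reproducibility.

``run_single_study`` executes the full post-processing chain
reject -> register -> average -> tensor fit -> eigensystem -> repair ->
FA/MD -> helix angle -> region labels -> regional summaries, either on a
simulated phantom acquisition or on a series read from disk.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import cardioframe, phantom, preprocess, reprostats, tensorfit
from .cardioframe import LVGeometryModel, RegionLabels
from .core import DWISeries, ScalarMap


@dataclass
class StudyResult:
    """Everything one study produces: maps, labels and summaries."""

    maps: dict[str, ScalarMap]
    eigensystem: tensorfit.EigenSystemField
    tensor_field: tensorfit.DiffusionTensorField
    labels: RegionLabels
    geometry: LVGeometryModel
    region_means: dict[str, pd.Series]
    rejection: preprocess.RejectionReport | None
    registration: preprocess.RegistrationResult | None
    truth: phantom.PhantomTruth | None = None

    def run_report(self) -> dict:
        """Machine-readable counts: masked, rejected, repaired."""
        return {
            "n_masked_voxels": int(self.eigensystem.mask.sum()),
            "n_rejected_frames": 0 if self.rejection is None else self.rejection.n_rejected,
            "n_repaired_eigenvalues": int(self.eigensystem.repaired.sum()),
        }


def analyze_series(
    series: DWISeries,
    geometry: LVGeometryModel,
    *,
    reject_threshold: float | None = preprocess.DEFAULT_REJECT_THRESHOLD,
    search_radius: int | None = preprocess.DEFAULT_SEARCH_RADIUS,
    s0_floor: float | None = None,
    truth: phantom.PhantomTruth | None = None,
) -> StudyResult:
    """Post-process one acquired (or simulated) series against a geometry."""
    averaged, rejection, registration = preprocess.preprocess(
        series,
        reject_threshold=reject_threshold,
        search_radius=search_radius,
    )
    tensor_field = tensorfit.fit_tensor_loglinear(averaged, s0_floor=s0_floor)
    # analysis is confined to the myocardium
    tensor_field.mask &= geometry.myocardium_mask
    eig = tensorfit.eigendecompose(tensor_field)
    eig = tensorfit.repair_negative_eigenvalues(eig)
    fa = tensorfit.compute_fa(eig)
    md = tensorfit.compute_md(eig)
    ha = cardioframe.helix_angle_map(eig, geometry)
    labels = cardioframe.build_labels(geometry)
    maps = {"FA": fa, "MD": md, "HA": ha}
    region_means = {k: reprostats.regional_means(m, labels) for k, m in maps.items()}
    return StudyResult(
        maps=maps,
        eigensystem=eig,
        tensor_field=tensor_field,
        labels=labels,
        geometry=geometry,
        region_means=region_means,
        rejection=rejection,
        registration=registration,
        truth=truth,
    )


def run_single_study(
    config: phantom.PhantomConfig,
    *,
    seed: int | None = None,
    reject_threshold: float | None = preprocess.DEFAULT_REJECT_THRESHOLD,
    search_radius: int | None = preprocess.DEFAULT_SEARCH_RADIUS,
    s0_floor: float | None = None,
) -> StudyResult:
    """Simulate one phantom acquisition and post-process it."""
    series, truth = phantom.generate_study(config, seed=seed)
    return analyze_series(
        series,
        truth.geometry,
        reject_threshold=reject_threshold,
        search_radius=search_radius,
        s0_floor=s0_floor,
        truth=truth,
    )


def run_reproducibility(
    tables_initial: dict[str, pd.DataFrame] | None = None,
    tables_repeat: dict[str, pd.DataFrame] | None = None,
    *,
    paired: dict[str, tuple[pd.DataFrame, pd.DataFrame]] | None = None,
) -> dict[str, pd.DataFrame]:
    """Pair two cohorts' regional summaries into reproducibility tables.

    Accepts either explicit per-kind (subject x region) tables for the two
    scans, or the ``paired`` dict produced by
    :func:`cdtikit.reprostats.synthetic_paired_study`.
    """
    if paired is not None:
        return {
            kind: reprostats.paired_reproducibility(a, b)
            for kind, (a, b) in paired.items()
        }
    assert tables_initial is not None and tables_repeat is not None
    return {
        kind: reprostats.paired_reproducibility(tables_initial[kind], tables_repeat[kind])
        for kind in tables_initial
    }


def noiseless_config(config: phantom.PhantomConfig | None = None) -> phantom.PhantomConfig:
    """Copy of a phantom config with noise, shifts and corruption disabled."""
    import dataclasses

    base = config or phantom.PhantomConfig()
    return dataclasses.replace(base, noise_sigma=0.0, shift_sd=0.0, corrupt_prob=0.0)
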