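"""Repetition rejection, translation-only co-registration and averaging.

Mirrors the acquisition-side cleanup of a breath-hold cDTI protocol:
corrupted repetitions are dropped (scored by normalized cross-correlation
against the per-group median image, an automated stand-in for visual
review), the survivors are rigidly co-registered by integer translation
(no rotation) against the median b0 of each slice, and repetitions are
averaged per direction to recover SNR.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import DWISeries, InvalidParameterError, UnusableDataError

DEFAULT_REJECT_THRESHOLD = 0.90
DEFAULT_SEARCH_RADIUS = 10


@dataclass
class RejectionReport:
    """Per-frame similarity scores and accept/reject decisions."""

    scores: np.ndarray          # (slice, channel, repetition)
    accepted: np.ndarray        # bool, same shape
    threshold: float

    def to_frame(self) -> pd.DataFrame:
        s, c, r = np.indices(self.scores.shape)
        return pd.DataFrame(
            {
                "slice": s.ravel(),
                "channel": c.ravel(),
                "repetition": r.ravel(),
                "score": self.scores.ravel(),
                "accepted": self.accepted.ravel(),
                "threshold": self.threshold,
            }
        )

    @property
    def n_rejected(self) -> int:
        return int((~self.accepted).sum())


@dataclass
class RegistrationResult:
    """Estimated integer translations per frame (rotation is always zero)."""

    translations: np.ndarray    # (slice, channel, repetition, 2) as (drow, dcol)
    search_radius: int
    reference: str = "median accepted b0 per slice"

    def to_frame(self) -> pd.DataFrame:
        s, c, r = np.indices(self.translations.shape[:3])
        return pd.DataFrame(
            {
                "slice": s.ravel(),
                "channel": c.ravel(),
                "repetition": r.ravel(),
                "drow": self.translations[..., 0].ravel(),
                "dcol": self.translations[..., 1].ravel(),
                "reference": self.reference,
            }
        )


def _ncc(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation of two images, in [-1, 1]; 0 if either is flat."""
    a = a.ravel() - a.mean()
    b = b.ravel() - b.mean()
    denom = np.linalg.norm(a) * np.linalg.norm(b)
    if denom == 0:
        return 0.0
    return float(np.dot(a, b) / denom)


def reject_corrupted(
    series: DWISeries, threshold: float = DEFAULT_REJECT_THRESHOLD
) -> tuple[DWISeries, RejectionReport]:
    """Drop repetitions dissimilar to their (slice, channel) median image.

    Each accepted frame is scored by normalized cross-correlation against
    the pixelwise median over the currently accepted repetitions of its
    group; frames scoring below ``threshold`` are flagged rejected.  Raises
    :class:`UnusableDataError` if any group loses all repetitions.
    """
    if not -1 < threshold <= 1:
        raise InvalidParameterError("threshold must lie in (-1, 1]")
    arr = series.intensities
    n_s, _, _, n_ch, n_rep = arr.shape
    scores = np.full((n_s, n_ch, n_rep), np.nan)
    accepted = series.accepted.copy()
    for s in range(n_s):
        for ch in range(n_ch):
            reps = np.where(accepted[s, ch])[0]
            if reps.size == 0:
                raise UnusableDataError(
                    f"no accepted repetitions for slice {s}, channel {ch}"
                )
            median = np.median(arr[s, :, :, ch, reps], axis=0)
            for rep in reps:
                scores[s, ch, rep] = _ncc(arr[s, :, :, ch, rep], median)
            keep = scores[s, ch, reps] >= threshold
            accepted[s, ch, reps] = keep
            if not keep.any():
                raise UnusableDataError(
                    f"all repetitions rejected for slice {s}, channel {ch} "
                    f"(threshold {threshold})"
                )
    report = RejectionReport(scores=scores, accepted=accepted, threshold=threshold)
    return series.copy_with(accepted=accepted), report


def _xcorr_shift(
    reference: np.ndarray, image: np.ndarray, radius: int
) -> tuple[int, int]:
    """Integer shift of ``image`` maximizing cross-correlation with reference.

    Zero-mean circular cross-correlation evaluated by FFT; the peak is
    searched only within ``radius`` pixels of zero shift.  Returns the
    (drow, dcol) to APPLY to the image to align it with the reference.
    """
    ref = reference - reference.mean()
    img = image - image.mean()
    corr = np.fft.irfft2(
        np.fft.rfft2(ref) * np.conj(np.fft.rfft2(img)), s=ref.shape
    )
    offsets = np.arange(-radius, radius + 1)
    window = corr[np.ix_(offsets, offsets)]  # negative indices wrap
    k = np.unravel_index(np.argmax(window), window.shape)
    return int(offsets[k[0]]), int(offsets[k[1]])


def register_translation(
    series: DWISeries, search_radius: int = DEFAULT_SEARCH_RADIUS
) -> tuple[DWISeries, RegistrationResult]:
    """Translation-only co-registration of all accepted frames.

    The reference per slice is the pixelwise median of the accepted b0
    repetitions.  Each accepted frame is shifted by the integer translation
    (within ``search_radius``) maximizing its cross-correlation with that
    reference; shifted-in pixels are zero-filled.
    """
    from .phantom import _integer_shift

    if search_radius < 0:
        raise InvalidParameterError("search_radius must be >= 0")
    n_s, n_r, n_c, n_ch, n_rep = series.intensities.shape
    if search_radius > min(n_r, n_c) // 2:
        raise InvalidParameterError(
            f"search_radius {search_radius} exceeds half the grid"
        )
    arr = series.intensities.copy()
    translations = np.zeros((n_s, n_ch, n_rep, 2), dtype=int)
    for s in range(n_s):
        b0_reps = np.where(series.accepted[s, 0])[0]
        reference = np.median(arr[s, :, :, 0, b0_reps], axis=0)
        for ch in range(n_ch):
            for rep in np.where(series.accepted[s, ch])[0]:
                if search_radius == 0:
                    continue
                dr, dc = _xcorr_shift(reference, arr[s, :, :, ch, rep], search_radius)
                translations[s, ch, rep] = (dr, dc)
                if (dr, dc) != (0, 0):
                    arr[s, :, :, ch, rep] = _integer_shift(
                        arr[s, :, :, ch, rep], dr, dc
                    )
    result = RegistrationResult(translations=translations, search_radius=search_radius)
    return series.copy_with(intensities=arr), result


def average_repetitions(series: DWISeries) -> DWISeries:
    """Pixelwise mean over accepted repetitions, per (slice, channel).

    The output keeps a singleton repetition axis so downstream stages see
    the same array layout.
    """
    arr = series.intensities
    n_s, n_r, n_c, n_ch, _ = arr.shape
    out = np.empty((n_s, n_r, n_c, n_ch, 1))
    for s in range(n_s):
        for ch in range(n_ch):
            reps = np.where(series.accepted[s, ch])[0]
            if reps.size == 0:
                raise UnusableDataError(
                    f"no accepted repetitions for slice {s}, channel {ch}"
                )
            out[s, :, :, ch, 0] = arr[s, :, :, ch, reps].mean(axis=0)
    return series.copy_with(
        intensities=out,
        accepted=np.ones((n_s, n_ch, 1), dtype=bool),
    )


def preprocess(
    series: DWISeries,
    *,
    reject_threshold: float | None = DEFAULT_REJECT_THRESHOLD,
    search_radius: int | None = DEFAULT_SEARCH_RADIUS,
) -> tuple[DWISeries, RejectionReport | None, RegistrationResult | None]:
    """Reject, then co-register, then average — the full preprocessing stage.

    Pass ``reject_threshold=None`` or ``search_radius=None`` to skip a step.
    """
    report = None
    reg = None
    if reject_threshold is not None:
        series, report = reject_corrupted(series, reject_threshold)
    if search_radius is not None:
        series, reg = register_translation(series, search_radius)
    return average_repetitions(series), report, reg
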