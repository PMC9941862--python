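"""Signal conditioning before model fitting.

Depth/ROI-restricted Gaussian smoothing, discrete-cosine high-pass
filtering, percent-signal-change rescaling, and extraction of the
physiological nuisance regressors (respiration volume per time and cardiac
beats per minute) from belt and pulse-unit traces.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.signal import find_peaks

from .containers import FunctionalSeries, LabelVolume
from .depth import bin_layers

log = logging.getLogger(__name__)

__all__ = [
    "masked_gaussian_smooth",
    "dct_basis",
    "dct_highpass",
    "percent_signal_change",
    "rvt",
    "bpm",
]

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def smoothing_cells(labels: LabelVolume) -> list:
    """Masks of the (cortical depth bin, ROI) cells smoothing is confined to."""
    bins = bin_layers(labels.depth)
    cells = []
    for b in np.unique(bins[bins > 0]):
        for r in np.unique(labels.roi[labels.roi > 0]):
            mask = (bins == b) & (labels.roi == r)
            if mask.any():
                cells.append(mask)
    return cells


def masked_gaussian_smooth(
    series: FunctionalSeries,
    labels: LabelVolume,
    fwhm_mm: float = 2.35,
) -> FunctionalSeries:
    """Gaussian smoothing restricted to each (depth bin, ROI) cell.

    Within a cell the kernel is renormalised over the in-cell voxels only
    (so a constant image is preserved and no signal leaks between cells);
    voxels outside every cell are passed through unchanged.
    """
    if fwhm_mm <= 0:
        raise ValueError("fwhm_mm must be positive")
    sigma_vox = tuple(
        fwhm_mm * FWHM_TO_SIGMA / vs for vs in series.voxel_size_mm
    )
    data = np.asarray(series.data, np.float64)
    out = data.copy()
    cells = smoothing_cells(labels)
    if not cells:
        log.warning("no smoothing cells found; series passed through unsmoothed")
    for mask in cells:
        axes_idx = (
            np.flatnonzero(mask.any(axis=(1, 2))),
            np.flatnonzero(mask.any(axis=(0, 2))),
            np.flatnonzero(mask.any(axis=(0, 1))),
        )
        pad = [int(np.ceil(4 * s)) for s in sigma_vox]
        sl = tuple(
            slice(max(idx.min() - p, 0), idx.max() + p + 1)
            for idx, p in zip(axes_idx, pad)
        )
        sub_mask = mask[sl].astype(np.float64)
        weights = gaussian_filter(sub_mask, sigma_vox, mode="constant")
        num = gaussian_filter(
            data[sl] * sub_mask[..., None], sigma=(*sigma_vox, 0.0), mode="constant"
        )
        inside = mask[sl]
        out[sl][inside] = num[inside] / weights[inside][:, None]
    return FunctionalSeries(out, tr=series.tr, voxel_size_mm=series.voxel_size_mm)


def dct_basis(n_samples: int, tr: float, cutoff_hz: float) -> np.ndarray:
    """The K lowest-frequency DCT-II vectors below ``cutoff_hz``, unit-normalised.

    ``K = floor(2 * duration * cutoff_hz)``; basis vector k covers k/2
    cosine cycles over the record, i.e. frequency ``k / (2 * duration)``.
    """
    if cutoff_hz <= 0:
        raise ValueError("cutoff_hz must be positive")
    duration = n_samples * tr
    k_max = int(np.floor(2.0 * duration * cutoff_hz))
    if k_max >= n_samples:
        raise ValueError(
            f"cutoff {cutoff_hz} Hz retains {k_max} basis vectors for only "
            f"{n_samples} samples"
        )
    t = np.arange(n_samples)
    basis = np.stack(
        [np.cos(np.pi * k * (2 * t + 1) / (2 * n_samples)) for k in range(1, k_max + 1)],
        axis=1,
    ) if k_max else np.empty((n_samples, 0))
    norms = np.linalg.norm(basis, axis=0)
    return basis / norms if k_max else basis


def dct_highpass(data: np.ndarray, tr: float, cutoff_hz: float = 0.003) -> np.ndarray:
    """Regress the sub-cutoff DCT components out of each time course.

    The temporal mean (DC) is preserved so that percent-signal-change
    rescaling downstream stays well defined.  Idempotent (a projection).
    Time runs along the last axis.
    """
    data = np.asarray(data, float)
    basis = dct_basis(data.shape[-1], tr, cutoff_hz)
    if basis.shape[1] == 0:
        return data.copy()
    coeffs = data @ basis  # orthonormal columns
    return data - coeffs @ basis.T


def percent_signal_change(data: np.ndarray, return_valid: bool = False):
    """Rescale each voxel time course to percent change about its temporal mean.

    Voxels with non-positive mean are flagged invalid and set to NaN.
    Time runs along the last axis.
    """
    data = np.asarray(data, float)
    mean = data.mean(axis=-1, keepdims=True)
    valid = mean[..., 0] > 0
    n_bad = int((~valid).sum())
    if n_bad:
        log.warning("percent_signal_change: %d voxels with non-positive mean", n_bad)
    with np.errstate(divide="ignore", invalid="ignore"):
        psc = 100.0 * (data - mean) / mean
    psc[~valid] = np.nan
    if return_valid:
        return psc, valid
    return psc


def _cycle_metrics(trace, sample_rate_hz, expected_period_s, kind):
    trace = np.asarray(trace, float)
    if len(trace) < 2 * expected_period_s * sample_rate_hz:
        raise ValueError(f"{kind} trace shorter than two expected cycles")
    distance = max(1, int(round(0.5 * expected_period_s * sample_rate_hz)))
    peaks, _ = find_peaks(trace, distance=distance)
    if len(peaks) < 2:
        raise ValueError(f"no detectable {kind} cycles in trace")
    t = np.arange(len(trace)) / sample_rate_hz
    periods = np.diff(t[peaks])
    mids = 0.5 * (t[peaks][:-1] + t[peaks][1:])
    return trace, t, peaks, periods, mids


def rvt(
    respiration,
    sample_rate_hz: float,
    volume_times,
    expected_period_s: float = 3.5,
) -> np.ndarray:
    """Respiration volume per time, interpolated to the volume grid.

    Per breath (peak-to-peak interval): (peak minus trough amplitude)
    divided by the breath period; a pure sinusoid of amplitude A and period
    T gives the constant 2A/T.
    """
    trace, t, peaks, periods, mids = _cycle_metrics(
        respiration, sample_rate_hz, expected_period_s, "respiration"
    )
    values = np.empty(len(periods))
    for i in range(len(periods)):
        seg = trace[peaks[i]: peaks[i + 1] + 1]
        values[i] = (trace[peaks[i]] - seg.min()) / periods[i]
    return np.interp(np.asarray(volume_times, float), mids, values)


def bpm(
    pulse,
    sample_rate_hz: float,
    volume_times,
    expected_period_s: float = 0.9,
) -> np.ndarray:
    """Cardiac beats per minute (60 / inter-beat interval) on the volume grid."""
    _, t, peaks, periods, mids = _cycle_metrics(
        pulse, sample_rate_hz, expected_period_s, "pulse"
    )
    return np.interp(np.asarray(volume_times, float), mids, 60.0 / periods)
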