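"""Pulse-wave phase maps, arteriovenous delays and amplitude maps.

After phase-resolved reconstruction every voxel carries a signal waveform
sampled at ``n_phases`` points of the cardiac cycle.  The phase map records,
per voxel, how many phases its signal maximum lags the whole-brain signal
maximum (wrapped modulo ``n_phases``).  The arteriovenous delay of a
vascular territory is the phase difference between the earliest-peaking
voxels of that territory and of the superior sagittal sinus, converted to
milliseconds via the median R-R interval.  Amplitude maps subtract the phase
with the lowest brain-mean signal from every phase; the amplitude at the
brain-wide maximum phase, divided by the mean signal, gives the pulsatility
style signal contrast in percent.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.ndimage import binary_fill_holes
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.transform import resize

from .errors import ConfigurationError, MaskError, NumericError, RoiError
from .gating import CycleStats
from .recon import PhaseResolvedSeries

__all__ = [
    "PhaseMap",
    "AmplitudeMaps",
    "RoiSet",
    "brain_mask",
    "phase_map",
    "arteriovenous_delays",
    "amplitude_maps",
    "signal_contrast",
    "phase_to_ms",
]

TERRITORIES = ("aca_l", "aca_r", "mca_l", "mca_r", "pca_l", "pca_r")


@dataclass(frozen=True)
class PhaseMap:
    """Per-voxel pulse-wave arrival phase relative to the brain-wide peak.

    ``phase_delta`` is ``(argmax_voxel - global_max_phase) mod n_phases``,
    defined only inside ``brain_mask`` (-1 outside).  ``is_flat`` flags a
    series whose brain-mean signal barely varies across phases (no cardiac
    modulation detectable), in which case the deltas are noise.
    """

    phase_delta: np.ndarray
    brain_mask: np.ndarray
    global_max_phase: int
    n_phases: int
    is_flat: bool = False


@dataclass(frozen=True)
class AmplitudeMaps:
    """Per-phase amplitude images relative to the minimum-signal phase."""

    per_phase: np.ndarray  # (n_phases, H, W)
    min_phase: int
    global_max_phase: int
    comparison_map: np.ndarray
    comparison_mode: str
    normalization: dict


@dataclass(frozen=True)
class RoiSet:
    """Named boolean masks: vascular territories, sinus, tissue classes."""

    masks: Mapping[str, np.ndarray]

    def __getitem__(self, name: str) -> np.ndarray:
        return self.masks[name]

    def __contains__(self, name: str) -> bool:
        return name in self.masks

    def resize_to(self, shape: tuple[int, int]) -> "RoiSet":
        """Nearest-neighbour resample of every mask to a new grid."""
        out = {
            k: resize(m.astype(float), shape, order=0, anti_aliasing=False) > 0.5
            for k, m in self.masks.items()
        }
        return RoiSet(out)


def brain_mask(mean_signal_image: np.ndarray, method: str = "otsu") -> np.ndarray:
    """Threshold the mean-signal image and keep the filled main component."""
    img = np.asarray(mean_signal_image, dtype=float)
    if np.any(img < 0):
        raise ConfigurationError("mean-signal image must be non-negative")
    if method != "otsu":
        raise ConfigurationError(f"unknown masking method {method!r}")
    if np.ptp(img) == 0:
        raise MaskError("flat image: no brain/background separation")
    thr = threshold_otsu(img)
    above = img > thr
    if not above.any():
        raise MaskError("empty brain mask")
    labels = cc_label(above)
    largest = np.argmax(np.bincount(labels.ravel())[1:]) + 1
    return binary_fill_holes(labels == largest)


def _brain_mean_curve(series: PhaseResolvedSeries, mask: np.ndarray) -> np.ndarray:
    return series.images[:, mask].mean(axis=1)


def phase_map(
    series: PhaseResolvedSeries,
    mask: np.ndarray,
    flat_rel_tol: float = 1e-3,
) -> PhaseMap:
    """Map each voxel's maximum-signal phase against the brain's.

    Ties at the maximum resolve to the earliest phase index.  If the
    brain-mean signal varies across phases by less than ``flat_rel_tol`` of
    its level the map is flagged flat (``is_flat``).
    """
    if series.n_phases < 2:
        raise ConfigurationError("need at least 2 cardiac phases")
    if not mask.any():
        raise MaskError("empty brain mask")
    curve = _brain_mean_curve(series, mask)
    global_max = int(np.argmax(curve))
    vox_arg = np.argmax(series.images, axis=0)
    delta = np.full(mask.shape, -1, dtype=int)
    delta[mask] = (vox_arg[mask] - global_max) % series.n_phases
    flat = bool(np.ptp(curve) <= flat_rel_tol * max(curve.mean(), np.finfo(float).tiny))
    return PhaseMap(delta, mask, global_max, series.n_phases, is_flat=flat)


def _earliest_phase(pmap: PhaseMap, roi: np.ndarray, wrap: str) -> int:
    """Earliest (signed) phase delta inside a ROI.

    With ``wrap="signed"`` (default) deltas beyond half a cycle are treated
    as arrivals *before* the reference (delta - n_phases), so a voxel peaking
    one phase before the global maximum counts as -1, not n_phases - 1; the
    pure modulo reading is available with ``wrap="modulo"``.
    """
    d = pmap.phase_delta[roi & pmap.brain_mask]
    if d.size == 0:
        raise RoiError("ROI has no voxels inside the brain mask")
    if wrap == "signed":
        d = np.where(d > pmap.n_phases / 2, d - pmap.n_phases, d)
    elif wrap != "modulo":
        raise ConfigurationError(f"unknown wrap mode {wrap!r}")
    return int(d.min())


def _roi_curve_phase(
    series: PhaseResolvedSeries, pmap: PhaseMap, roi: np.ndarray, wrap: str
) -> int:
    """Peak phase of the ROI-mean waveform, signed relative to the brain peak."""
    m = roi & pmap.brain_mask
    if not m.any():
        raise RoiError("ROI has no voxels inside the brain mask")
    curve = series.images[:, m].mean(axis=1)
    d = (int(np.argmax(curve)) - pmap.global_max_phase) % pmap.n_phases
    if wrap == "signed" and d > pmap.n_phases / 2:
        d -= pmap.n_phases
    return d


def arteriovenous_delays(
    pmap: PhaseMap,
    rois: RoiSet,
    stats: CycleStats,
    wrap: str = "signed",
    group: str | None = None,
    series: PhaseResolvedSeries | None = None,
    method: str = "auto",
) -> pd.DataFrame:
    """Arteriovenous delay per territory, in phases and milliseconds.

    For each arterial territory T the delay is
    ``(earliest_SSS - earliest_T) mod n_phases`` converted with the median
    R-R interval: the time the pulse wave needs from the territory's
    earliest-arriving voxels to the superior sagittal sinus.

    ``method`` selects how a ROI's arrival phase is estimated:
    ``"roi_curve"`` (default when ``series`` is given) takes the peak of the
    ROI-mean signal waveform — the phase difference of the two waveform
    maxima, robust because voxel noise averages out; ``"voxel_min"`` takes
    the wrap-aware minimum per-voxel phase delta, which tracks the single
    earliest voxel but is an order statistic of the noise.
    """
    if method == "auto":
        method = "roi_curve" if series is not None else "voxel_min"
    if method == "roi_curve" and series is None:
        raise ConfigurationError("method 'roi_curve' needs the phase series")
    if method not in ("roi_curve", "voxel_min"):
        raise ConfigurationError(f"unknown delay method {method!r}")
    if "sinus" not in rois:
        raise RoiError("RoiSet lacks a 'sinus' mask")

    def _phase_of(roi: np.ndarray) -> int:
        if method == "roi_curve":
            return _roi_curve_phase(series, pmap, roi, wrap)
        return _earliest_phase(pmap, roi, wrap)

    earliest_sss = _phase_of(rois["sinus"])
    rows = []
    for terr in TERRITORIES:
        if terr not in rois:
            raise RoiError(f"RoiSet lacks territory {terr!r}")
        if not rois[terr].any():
            raise RoiError(f"territory {terr!r} is empty")
        earliest = _phase_of(rois[terr])
        delay_phases = (earliest_sss - earliest) % pmap.n_phases
        rows.append(
            {
                "territory": terr,
                "earliest_phase": earliest,
                "delay_phases": int(delay_phases),
                "delay_ms": phase_to_ms(int(delay_phases), stats, pmap.n_phases),
            }
        )
    table = pd.DataFrame(rows)
    if group is not None:
        table["group"] = group
    return table


def amplitude_maps(
    series: PhaseResolvedSeries,
    mask: np.ndarray,
    comparison_mode: str = "global_max",
) -> AmplitudeMaps:
    """Subtract the minimum-signal phase from every phase image.

    ``min_phase`` is the phase with the lowest brain-mean signal, so
    ``per_phase[min_phase]`` is identically zero.  The comparison map used
    against perfusion imaging is the amplitude at the brain-wide maximum
    phase (default) or the per-voxel maximum over phases
    (``comparison_mode="voxel_max"``, noisier).
    """
    if series.n_phases < 2:
        raise ConfigurationError("need at least 2 cardiac phases")
    if not mask.any():
        raise MaskError("empty brain mask")
    curve = _brain_mean_curve(series, mask)
    min_phase = int(np.argmin(curve))
    global_max = int(np.argmax(curve))
    per_phase = series.images - series.images[min_phase]
    if comparison_mode == "global_max":
        comparison = per_phase[global_max].copy()
    elif comparison_mode == "voxel_max":
        comparison = per_phase.max(axis=0)
    else:
        raise ConfigurationError(f"unknown comparison_mode {comparison_mode!r}")
    return AmplitudeMaps(
        per_phase=per_phase,
        min_phase=min_phase,
        global_max_phase=global_max,
        comparison_map=comparison,
        comparison_mode=comparison_mode,
        normalization={},
    )


def signal_contrast(
    amps: AmplitudeMaps, mean_signal_image: np.ndarray, roi: np.ndarray
) -> float:
    """Mean pulse amplitude over a ROI as a percentage of the mean signal.

    The analogue of the sonographic pulsatility index:
    ``100 * mean(amplitude) / mean(signal)`` over the ROI.
    """
    if not roi.any():
        raise RoiError("empty ROI for signal contrast")
    denom = float(mean_signal_image[roi].mean())
    if denom <= 0:
        raise NumericError("mean signal is not positive on the ROI")
    return 100.0 * float(amps.comparison_map[roi].mean()) / denom


def phase_to_ms(delay_phases: int, stats: CycleStats, n_phases: int) -> float:
    """Convert a phase-count delay to milliseconds via the median R-R."""
    if not 0 <= delay_phases < n_phases:
        raise ConfigurationError("delay_phases must lie in [0, n_phases)")
    return delay_phases * stats.median_rr_ms / n_phases
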