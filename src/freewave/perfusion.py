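"""ASL perfusion maps and agreement statistics against pulse-amplitude maps.

Perfusion-weighted maps are averaged control-minus-label subtractions.  For
spatial agreement with the flow-related-enhancement amplitude maps, both are
binarized at the 40th percentile of in-mask values (matching the average
gray/white volume fraction) and compared per tissue class with the
Sørensen-Dice coefficient; voxelwise association uses Pearson correlation
with a Fisher-Z significance test.  Group comparisons of arteriovenous
delays use the Mann-Whitney U test; paired contrast comparisons between the
two modalities use the Wilcoxon signed-rank test.  A closed-form single
compartment CBF calibration (consensus "white paper" model) is included.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .errors import ConfigurationError, InputError, NumericError

__all__ = [
    "PcaslSeries",
    "BinaryTissueMap",
    "AgreementReport",
    "pcasl_subtraction_map",
    "normalize_p90",
    "binarize_p40",
    "dice_by_class",
    "voxelwise_pearson",
    "group_compare",
    "paired_compare",
    "white_paper_cbf",
]


@dataclass(frozen=True)
class PcaslSeries:
    """Paired control and label magnitude image series."""

    control: np.ndarray  # (n_pairs, H, W)
    label: np.ndarray  # (n_pairs, H, W)
    m0: np.ndarray | None = None
    label_duration_ms: float = 1800.0
    post_label_delay_ms: float = 1800.0

    def __post_init__(self):
        c = np.asarray(self.control, dtype=float)
        l = np.asarray(self.label, dtype=float)
        if c.shape != l.shape or c.ndim != 3:
            raise InputError("control and label series must be equal-shaped stacks")
        object.__setattr__(self, "control", c)
        object.__setattr__(self, "label", l)

    @property
    def n_pairs(self) -> int:
        return self.control.shape[0]


@dataclass(frozen=True)
class BinaryTissueMap:
    """Percentile-thresholded perfusion/amplitude map (True = 'gray')."""

    high: np.ndarray  # boolean, defined inside mask
    mask: np.ndarray
    threshold: float
    percentile: float

    @property
    def high_fraction(self) -> float:
        return float(self.high[self.mask].mean())


@dataclass(frozen=True)
class AgreementReport:
    """Agreement between an amplitude map and a perfusion map."""

    dice_gray: float
    dice_white: float
    pearson_r: float
    fisher_z: float
    p_value: float
    mismatch_map: np.ndarray


def pcasl_subtraction_map(series: PcaslSeries):
    """Average control-minus-label map and the overall mean-signal image.

    Returns
    -------
    (ndarray, ndarray)
        The perfusion-weighted map (mean over pairs of control - label) and
        the mean signal over all control and label images together.
    """
    if series.n_pairs < 1:
        raise InputError("need at least one control/label pair")
    sub = (series.control - series.label).mean(axis=0)
    mean_signal = np.concatenate([series.control, series.label]).mean(axis=0)
    return sub, mean_signal


def normalize_p90(map_: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Divide by the 90th percentile of in-mask values, then clip at 1."""
    if not mask.any():
        raise InputError("empty mask")
    p90 = float(np.percentile(map_[mask], 90))
    if p90 <= 0:
        raise NumericError("90th percentile is not positive")
    return np.minimum(map_ / p90, 1.0)


def binarize_p40(map_: np.ndarray, mask: np.ndarray, percentile: float = 40.0) -> BinaryTissueMap:
    """Threshold at the in-mask 40th percentile (linear interpolation).

    Voxels strictly above the threshold are 'highly perfused' (gray matter
    like); with all-distinct values the high fraction is ~0.6, the average
    gray/white volume ratio the threshold encodes.
    """
    if not mask.any():
        raise InputError("empty mask")
    vals = map_[mask]
    if np.ptp(vals) == 0:
        raise NumericError("degenerate map: all in-mask values equal")
    thr = float(np.percentile(vals, percentile))
    high = np.zeros(mask.shape, dtype=bool)
    high[mask] = map_[mask] > thr
    return BinaryTissueMap(high=high, mask=mask, threshold=thr, percentile=percentile)


def dice_by_class(a: BinaryTissueMap, b: BinaryTissueMap):
    """Sørensen-Dice per tissue class plus a voxelwise mismatch map.

    ``dice_gray`` compares the above-threshold (True) voxels, ``dice_white``
    the below-threshold voxels within the shared mask.  A class empty in
    both maps yields NaN for that class.
    """
    if a.mask.shape != b.mask.shape or not np.array_equal(a.mask, b.mask):
        raise InputError("binary maps must share one grid and mask")
    mask = a.mask

    def _dice(x: np.ndarray, y: np.ndarray) -> float:
        nx, ny = int(x.sum()), int(y.sum())
        if nx + ny == 0:
            return float("nan")
        return 2.0 * int((x & y).sum()) / (nx + ny)

    gray = _dice(a.high & mask, b.high & mask)
    white = _dice(~a.high & mask, ~b.high & mask)
    mismatch = np.zeros(mask.shape, dtype=bool)
    mismatch[mask] = a.high[mask] != b.high[mask]
    return gray, white, mismatch


def voxelwise_pearson(map_a: np.ndarray, map_b: np.ndarray, mask: np.ndarray):
    """Pearson r over in-mask voxels with a Fisher-Z significance test.

    ``z = atanh(r)`` is compared to a normal null with sd ``1/sqrt(n - 3)``
    (two-sided).  Spatial autocorrelation is ignored, so the nominal p-value
    treats every voxel as independent.
    """
    x = np.asarray(map_a, dtype=float)[mask]
    y = np.asarray(map_b, dtype=float)[mask]
    if x.size < 3:
        raise InputError("need at least 3 in-mask voxels")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise NumericError("zero variance in one of the maps")
    r = float(sps.pearsonr(x, y).statistic)
    z = math.atanh(min(max(r, -1 + 1e-15), 1 - 1e-15))
    se = 1.0 / math.sqrt(x.size - 3)
    p = 2.0 * sps.norm.sf(abs(z) / se)
    return r, z, float(p)


def group_compare(delays_group_a, delays_group_b):
    """Mann-Whitney U test between two independent delay samples.

    Exact null enumeration for combined n <= 20 without ties, otherwise the
    normal approximation with tie correction.  Returns (U of sample A,
    two-sided p).
    """
    a = np.asarray(delays_group_a, dtype=float)
    b = np.asarray(delays_group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise InputError("both samples must be nonempty")
    has_ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    method = "exact" if (a.size + b.size <= 20 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def paired_compare(values_a, values_b):
    """Wilcoxon signed-rank test for paired samples.

    Exact sign-permutation null for up to 15 nonzero differences, normal
    approximation (midranks, tie-corrected variance) beyond.  Zero
    differences are discarded.  Returns (W statistic, two-sided p).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape:
        raise InputError("paired samples must have equal length")
    diff = a - b
    nz = diff[diff != 0]
    if nz.size == 0:
        raise NumericError("all paired differences are zero")
    mode = "exact" if nz.size <= 15 else "approx"
    res = sps.wilcoxon(a, b, zero_method="wilcox", alternative="two-sided", mode=mode)
    return float(res.statistic), float(res.pvalue)


def white_paper_cbf(
    perfusion_map: np.ndarray,
    m0_image: np.ndarray,
    label_duration_ms: float = 1800.0,
    pld_ms: float = 1800.0,
    t1_blood_s: float = 1.65,
    alpha: float = 0.85,
    lam: float = 0.9,
):
    """Closed-form single-compartment CBF calibration in ml/100g/min.

    ``CBF = 6000 * lam * dM * exp(PLD/T1b) /
    (2 * alpha * T1b * M0 * (1 - exp(-tau/T1b)))`` with the label duration
    ``tau`` and post-labeling delay in seconds.  Voxels with non-positive M0
    are masked out (CBF set to 0) and their count returned.
    """
    dm = np.asarray(perfusion_map, dtype=float)
    m0 = np.asarray(m0_image, dtype=float)
    if dm.shape != m0.shape:
        raise InputError("perfusion map and M0 image must share a grid")
    tau = label_duration_ms / 1000.0
    pld = pld_ms / 1000.0
    valid = m0 > 0
    cbf = np.zeros_like(dm)
    denom = 2.0 * alpha * t1_blood_s * m0[valid] * (1.0 - math.exp(-tau / t1_blood_s))
    cbf[valid] = 6000.0 * lam * dm[valid] * math.exp(pld / t1_blood_s) / denom
    return cbf, int((~valid).sum())
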