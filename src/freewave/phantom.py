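"""Synthetic brain-slice phantom and raw-data simulators.

Generates everything the post-processing chain consumes, with known ground
truth: a compartmental 2-D brain phantom (white matter, cortical gray-matter
rim, ventricular CSF, six arterial territory vessels, superior sagittal
sinus), a pulse-oximeter sawtooth with configurable heart rate and R-R
jitter, a line-by-line multi-coil Cartesian k-space acquisition whose
instantaneous signal is cardiac-modulated by flow-related enhancement, and a
pCASL-like control/label magnitude series.

Signal model
------------
Each voxel's instantaneous magnitude is

    I(x, t) = S0(x) * (1 - beta * exp(-r / tau)) * (1 + A(x) * w(u(x, t)))

where ``S0`` is the compartment baseline, the middle factor is the transient
approach to bSSFP steady state over repetition index ``r``, ``A`` is the
cardiac modulation amplitude (fraction of baseline), and ``w`` is a smooth
unimodal pulse waveform (raised cosine, peak 1 at phase 0).  The waveform
argument is the cycle fraction relative to the compartment's arrival time:
``u = ((t - T_j - phi(x)) mod RR_j) / RR_j`` with ``T_j`` the start of the
current cardiac cycle and ``RR_j`` its length, so the pulse wave arrives a
fixed ``phi`` milliseconds after each trigger even when the R-R interval
jitters.  Readout ``k`` of repetition ``r`` (acquired at ``(r*n_pe + k)*TR``)
stores row ``k`` of the centered unitary 2-D DFT of ``I(.,t)`` times the coil
sensitivity, plus complex Gaussian noise: because the modulation is
piecewise-constant per compartment the line is assembled exactly as a linear
combination of a handful of precomputed static transforms, keeping the
simulation fast without approximating the line-by-line time dependence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from ._fft import cfft2
from .errors import ConfigurationError, SimulationError
from .gating import PmuTrace

__all__ = [
    "COMPARTMENTS",
    "ARTERIES",
    "LABELS",
    "PhantomConfig",
    "PhantomTruth",
    "AcquisitionConfig",
    "KSpaceSeries",
    "make_phantom",
    "simulate_pmu",
    "simulate_kspace",
    "simulate_pcasl",
    "raised_cosine",
]

COMPARTMENTS = (
    "background", "white", "gray", "csf",
    "aca_l", "aca_r", "mca_l", "mca_r", "pca_l", "pca_r", "sinus",
)
ARTERIES = ("aca_l", "aca_r", "mca_l", "mca_r", "pca_l", "pca_r")
LABELS = {name: code for code, name in enumerate(COMPARTMENTS)}

# Baselines in arbitrary magnitude units; amplitudes as fractions of baseline;
# arrivals as ms after the cardiac trigger.  Amplitudes put the whole-brain
# pulsatility (signal contrast) in the few-tenths-of-a-percent range typical
# of parenchyma, with vessels an order of magnitude stronger.
_DEFAULT_BASELINE = {
    "background": 0.0, "white": 1.0, "gray": 1.2, "csf": 1.5,
    "aca_l": 1.8, "aca_r": 1.8, "mca_l": 1.8, "mca_r": 1.8,
    "pca_l": 1.8, "pca_r": 1.8, "sinus": 1.8,
}
_DEFAULT_AMPLITUDE = {
    "background": 0.0, "white": 0.004, "gray": 0.008, "csf": 0.012,
    "aca_l": 0.06, "aca_r": 0.06, "mca_l": 0.06, "mca_r": 0.06,
    "pca_l": 0.06, "pca_r": 0.06, "sinus": 0.05,
}
_DEFAULT_ARRIVAL_MS = {
    "background": 0.0, "white": 300.0, "gray": 300.0, "csf": 350.0,
    "aca_l": 200.0, "aca_r": 200.0, "mca_l": 200.0, "mca_r": 200.0,
    "pca_l": 200.0, "pca_r": 200.0, "sinus": 550.0,
}


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry and physiology of the synthetic brain slice.

    ``baseline``, ``modulation_amplitude`` and ``arrival_time_ms`` are
    per-compartment overrides merged over the defaults above.  The steady
    state transient is ``1 - beta*exp(-r/tau)`` in repetition index ``r``
    (defaults make it negligible after ~10 repetitions).  ``duty`` is the
    fraction of the cardiac cycle occupied by the raised-cosine pulse wave.
    """

    n_pe: int = 128
    n_fe: int = 128
    n_coils: int = 4
    baseline: Mapping[str, float] = field(default_factory=dict)
    modulation_amplitude: Mapping[str, float] = field(default_factory=dict)
    arrival_time_ms: Mapping[str, float] = field(default_factory=dict)
    steady_state_beta: float = 0.5
    steady_state_tau: float = 1.0
    duty: float = 0.3
    coil_sigma_rel: float = 0.6
    coil_floor: float = 0.1


@dataclass(frozen=True)
class PhantomTruth:
    """Ground truth of a simulated brain slice."""

    label_map: np.ndarray
    baseline: dict
    modulation_amplitude: dict
    arrival_time_ms: dict
    steady_state_beta: float
    steady_state_tau: float
    duty: float
    coil_sensitivities: np.ndarray  # (n_coils, n_pe, n_fe)

    @property
    def shape(self) -> tuple[int, int]:
        return self.label_map.shape

    @property
    def n_coils(self) -> int:
        return self.coil_sensitivities.shape[0]

    def compartment_mask(self, name: str) -> np.ndarray:
        return self.label_map == LABELS[name]

    @property
    def brain_mask(self) -> np.ndarray:
        return self.label_map != LABELS["background"]

    def _per_compartment_image(self, values: Mapping[str, float]) -> np.ndarray:
        lut = np.array([values[name] for name in COMPARTMENTS], dtype=float)
        return lut[self.label_map]

    def baseline_image(self) -> np.ndarray:
        return self._per_compartment_image(self.baseline)

    def amplitude_image(self) -> np.ndarray:
        return self._per_compartment_image(self.modulation_amplitude)

    def arrival_image(self) -> np.ndarray:
        return self._per_compartment_image(self.arrival_time_ms)

    def roi_set(self, erode: int = 0, erode_vessels: int = 0, dilate_vessels: int = 0):
        """Territory / tissue ROI masks derived from the truth labels.

        Returns a :class:`freewave.pulsemaps.RoiSet` on the phantom grid;
        resize with ``RoiSet.resize_to`` to match a reconstructed grid.
        ``erode`` shrinks the gray/white tissue masks away from compartment
        borders; ``erode_vessels`` keeps only vessel cores (the way delay
        ROIs are drawn on clean vessel centers, avoiding partial-volume rim
        voxels); ``dilate_vessels`` grows the territory masks instead.
        """
        from scipy.ndimage import binary_dilation, binary_erosion

        from .pulsemaps import RoiSet

        masks = {}
        for name in ARTERIES + ("sinus",):
            m = self.compartment_mask(name)
            if erode_vessels:
                m = binary_erosion(m, iterations=erode_vessels)
            if dilate_vessels:
                m = binary_dilation(m, iterations=dilate_vessels) & self.brain_mask
            masks[name] = m
        for name in ("gray", "white"):
            m = self.compartment_mask(name)
            if erode:
                m = binary_erosion(m, iterations=erode)
            masks[name] = m
        masks["brain"] = self.brain_mask
        return RoiSet(masks)


def _merge(defaults: Mapping[str, float], overrides: Mapping[str, float]) -> dict:
    unknown = set(overrides) - set(COMPARTMENTS)
    if unknown:
        raise ConfigurationError(f"unknown compartment(s): {sorted(unknown)}")
    merged = dict(defaults)
    merged.update(overrides)
    return merged


def _ellipse(shape, center, semi_axes) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return ((rr - center[0]) / semi_axes[0]) ** 2 + (
        (cc - center[1]) / semi_axes[1]
    ) ** 2 <= 1.0


def _disc(shape, center, radius) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


def make_phantom(config: PhantomConfig = PhantomConfig()) -> PhantomTruth:
    """Build the compartment label map, parameter tables and coil maps.

    Deterministic given the configuration.  The brain is an ellipse with a
    cortical gray-matter rim and two ventricles; the six arterial territory
    vessels and the posterior sinus are small discs inside it.

    Raises
    ------
    ConfigurationError
        On grids smaller than 32, amplitudes outside [0, 1), non-finite
        parameters, or a sinus arrival not later than every arterial arrival.
    """
    n_pe, n_fe = config.n_pe, config.n_fe
    if n_pe < 32 or n_fe < 32:
        raise ConfigurationError("phantom grid must be at least 32 x 32")
    if config.n_coils < 1:
        raise ConfigurationError("need at least one coil")
    baseline = _merge(_DEFAULT_BASELINE, config.baseline)
    amplitude = _merge(_DEFAULT_AMPLITUDE, config.modulation_amplitude)
    arrival = _merge(_DEFAULT_ARRIVAL_MS, config.arrival_time_ms)
    for table in (baseline, amplitude, arrival):
        if not all(np.isfinite(v) for v in table.values()):
            raise ConfigurationError("compartment parameters must be finite")
    if not all(0.0 <= amplitude[c] < 1.0 for c in COMPARTMENTS):
        raise ConfigurationError("modulation amplitudes must lie in [0, 1)")
    if not all(arrival["sinus"] > arrival[a] for a in ARTERIES):
        raise ConfigurationError("sinus arrival must follow every arterial arrival")

    shape = (n_pe, n_fe)
    center = (n_pe / 2.0, n_fe / 2.0)
    label = np.zeros(shape, dtype=np.int16)
    outer = (0.42 * n_pe, 0.36 * n_fe)
    rim = 0.06 * min(n_pe, n_fe)
    brain = _ellipse(shape, center, outer)
    inner = _ellipse(shape, center, (outer[0] - rim, outer[1] - rim))
    label[brain] = LABELS["gray"]
    label[inner] = LABELS["white"]
    for dc in (-0.055, 0.055):
        vent = _ellipse(
            shape, (center[0], center[1] + dc * n_fe), (0.11 * n_pe, 0.035 * n_fe)
        )
        label[vent & inner] = LABELS["csf"]
    radius = max(2, round(min(n_pe, n_fe) / 42))
    vessel_pos = {
        "aca_l": (0.27, 0.45), "aca_r": (0.27, 0.55),
        "mca_l": (0.50, 0.17), "mca_r": (0.50, 0.83),
        "pca_l": (0.72, 0.42), "pca_r": (0.72, 0.58),
        "sinus": (0.80, 0.50),
    }
    for name, (fr, fc) in vessel_pos.items():
        disc = _disc(shape, (fr * n_pe, fc * n_fe), radius)
        label[disc & brain] = LABELS[name]

    # smooth non-negative coil lobes on a ring around the slice
    rr, cc = np.mgrid[:n_pe, :n_fe]
    sigma = config.coil_sigma_rel * min(n_pe, n_fe)
    ring = 0.75 * min(n_pe, n_fe) / 2.0
    coils = np.empty((config.n_coils, n_pe, n_fe))
    for c in range(config.n_coils):
        ang = 2.0 * np.pi * c / config.n_coils
        cr = center[0] + ring * np.sin(ang)
        cf = center[1] + ring * np.cos(ang)
        coils[c] = config.coil_floor + np.exp(
            -((rr - cr) ** 2 + (cc - cf) ** 2) / (2.0 * sigma**2)
        )

    return PhantomTruth(
        label_map=label,
        baseline=baseline,
        modulation_amplitude=amplitude,
        arrival_time_ms=arrival,
        steady_state_beta=config.steady_state_beta,
        steady_state_tau=config.steady_state_tau,
        duty=config.duty,
        coil_sensitivities=coils,
    )


@dataclass(frozen=True)
class AcquisitionConfig:
    """Cartesian line-by-line acquisition timing and noise.

    Defaults reproduce the reference protocol: 500 repetitions of 128
    phase-encode lines at TR 3.6 ms (total 3.84 min).  ``noise_sd`` is the
    per-component standard deviation of the complex Gaussian k-space noise,
    relative to the mean brain baseline; with the unitary DFT convention it
    equals the relative per-pixel noise of a single-repetition coil image, so
    ``noise_sd = 0.05`` corresponds to a per-repetition image SNR of 20.
    """

    n_pe: int = 128
    n_fe: int = 128
    n_repetitions: int = 500
    tr_ms: float = 3.6
    n_coils: int = 4
    noise_sd: float = 0.02
    pe_ordering: str = "sequential"
    seed: int = 0

    @property
    def n_readouts(self) -> int:
        return self.n_repetitions * self.n_pe

    @property
    def total_duration_ms(self) -> float:
        return self.n_readouts * self.tr_ms

    @property
    def total_duration_min(self) -> float:
        return self.total_duration_ms / 60000.0

    def pe_order(self) -> np.ndarray:
        """k-space row acquired at each line slot of a repetition."""
        if self.pe_ordering == "sequential":
            return np.arange(self.n_pe)
        if self.pe_ordering == "interleaved":
            return np.concatenate(
                [np.arange(0, self.n_pe, 2), np.arange(1, self.n_pe, 2)]
            )
        raise ConfigurationError(f"unknown pe_ordering {self.pe_ordering!r}")


@dataclass(frozen=True)
class KSpaceSeries:
    """Timestamped multi-coil Cartesian raw data over repetitions.

    ``data[r, s]`` is the line acquired at slot ``s`` of repetition ``r`` and
    belongs to k-space row ``pe_order[s]``; ``timestamps_ms[r, s]`` is its
    acquisition time.
    """

    data: np.ndarray  # (n_rep, n_pe, n_fe, n_coils) complex
    timestamps_ms: np.ndarray  # (n_rep, n_pe)
    tr_ms: float
    pe_order: np.ndarray  # (n_pe,)

    @property
    def n_repetitions(self) -> int:
        return self.data.shape[0]

    @property
    def n_pe(self) -> int:
        return self.data.shape[1]

    @property
    def n_fe(self) -> int:
        return self.data.shape[2]

    @property
    def n_coils(self) -> int:
        return self.data.shape[3]

    @property
    def n_readouts(self) -> int:
        return self.n_repetitions * self.n_pe

    def flat_timestamps(self) -> np.ndarray:
        return self.timestamps_ms.reshape(-1)

    def drop_repetitions(self, n: int) -> "KSpaceSeries":
        return KSpaceSeries(self.data[n:], self.timestamps_ms[n:], self.tr_ms, self.pe_order)


def raised_cosine(u: np.ndarray, duty: float = 0.3) -> np.ndarray:
    """Smooth unimodal pulse waveform on the unit circle, peak 1 at u = 0.

    ``w(u) = 0.5*(1 + cos(2*pi*d/duty))`` for circular distance ``d`` from 0
    below ``duty/2``, else 0.
    """
    if not 0 < duty <= 1:
        raise ConfigurationError("duty must lie in (0, 1]")
    u = np.asarray(u, dtype=float) % 1.0
    d = np.minimum(u, 1.0 - u)
    return np.where(d < duty / 2.0, 0.5 * (1.0 + np.cos(2.0 * np.pi * d / duty)), 0.0)


def simulate_pmu(
    heart_period_ms: float,
    jitter_sd_ms: float,
    duration_ms: float,
    sample_interval_ms: float = 3.6,
    seed: int = 0,
) -> PmuTrace:
    """Simulate the pulse-oximeter sawtooth over an acquisition.

    Trigger times start at 0 and accumulate i.i.d. Gaussian-jittered periods
    until the full duration (plus one spare cycle) is covered; samples on a
    regular ``sample_interval_ms`` grid record time since the latest trigger.
    Ground-truth trigger times ride along on the returned trace.

    Raises
    ------
    SimulationError
        If a jittered period comes out non-positive.
    """
    if heart_period_ms <= 0:
        raise SimulationError("heart period must be positive")
    if duration_ms <= 0 or sample_interval_ms <= 0:
        raise SimulationError("duration and sample interval must be positive")
    rng = np.random.default_rng(seed)
    triggers = [0.0]
    while triggers[-1] <= duration_ms + heart_period_ms:
        period = heart_period_ms + (
            rng.normal(0.0, jitter_sd_ms) if jitter_sd_ms > 0 else 0.0
        )
        if period <= 0:
            raise SimulationError("jitter produced a non-positive cardiac period")
        triggers.append(triggers[-1] + period)
    trig = np.asarray(triggers)
    n_samples = int(np.ceil(duration_ms / sample_interval_ms))
    t = np.arange(n_samples) * sample_interval_ms
    values = t - trig[np.searchsorted(trig, t, side="right") - 1]
    return PmuTrace(t, values, true_trigger_times_ms=trig)


def _modulated_compartments(phantom: PhantomTruth) -> list[str]:
    present = set(np.unique(phantom.label_map))
    return [
        name
        for name in COMPARTMENTS
        if phantom.modulation_amplitude[name] > 0 and LABELS[name] in present
    ]


def simulate_kspace(
    phantom: PhantomTruth,
    pmu: PmuTrace,
    acq: AcquisitionConfig = AcquisitionConfig(),
) -> KSpaceSeries:
    """Acquire the phantom line-by-line into multi-coil Cartesian k-space.

    Each readout sees the instantaneous cardiac-modulated image (see module
    docstring); stored lines are rows of the centered unitary 2-D DFT of the
    coil-weighted image plus complex Gaussian noise.  Requires the PMU trace
    to cover the full acquisition window.
    """
    n_pe, n_fe = acq.n_pe, acq.n_fe
    if phantom.shape != (n_pe, n_fe):
        raise ConfigurationError(
            f"phantom grid {phantom.shape} does not match acquisition "
            f"({n_pe}, {n_fe})"
        )
    if phantom.n_coils != acq.n_coils:
        raise ConfigurationError("phantom coil maps do not match acquisition n_coils")
    if pmu.true_trigger_times_ms is not None:
        trig = pmu.true_trigger_times_ms
    else:
        from .gating import detect_pmu_peaks

        trig = detect_pmu_peaks(pmu).trigger_times_ms
    total = acq.total_duration_ms
    if trig[0] > 0 or trig[-1] < total:
        raise ConfigurationError("PMU triggers do not cover the acquisition window")
    if len(pmu) < acq.n_readouts:
        raise ConfigurationError("PMU trace has fewer samples than readouts")

    order = acq.pe_order()
    t = (np.arange(acq.n_readouts) * acq.tr_ms).reshape(acq.n_repetitions, n_pe)
    cyc = np.searchsorted(trig, t.reshape(-1), side="right") - 1
    cyc = np.clip(cyc, 0, len(trig) - 2)
    rr = np.diff(trig)[cyc]
    since_trig = t.reshape(-1) - trig[cyc]

    comps = _modulated_compartments(phantom)
    base = phantom.baseline_image()
    sens = phantom.coil_sensitivities  # (C, pe, fe)
    # static transforms: baseline and one modulation basis image per compartment
    f_base = cfft2(base[None] * sens).transpose(1, 2, 0)  # (pe, fe, C)
    if comps:
        mod_imgs = np.stack(
            [
                base
                * phantom.modulation_amplitude[name]
                * phantom.compartment_mask(name)
                for name in comps
            ]
        )
        f_mod = cfft2(mod_imgs[:, None] * sens[None]).transpose(0, 2, 3, 1)
        # (M, pe, fe, C)
        w = np.empty((acq.n_readouts, len(comps)))
        for m, name in enumerate(comps):
            u = (since_trig - phantom.arrival_time_ms[name]) / rr
            w[:, m] = raised_cosine(u, phantom.duty)
        w = w.reshape(acq.n_repetitions, n_pe, len(comps))

    out = np.empty((acq.n_repetitions, n_pe, n_fe, acq.n_coils), dtype=complex)
    for s in range(n_pe):
        row = order[s]
        line = f_base[row][None]
        if comps:
            line = line + np.einsum("rm,mfc->rfc", w[:, s, :], f_mod[:, row])
        out[:, s] = line
    g = 1.0 - phantom.steady_state_beta * np.exp(
        -np.arange(acq.n_repetitions) / phantom.steady_state_tau
    )
    out *= g[:, None, None, None]

    if acq.noise_sd > 0:
        rng = np.random.default_rng(acq.seed)
        ref = float(base[phantom.brain_mask].mean())
        sd = acq.noise_sd * ref
        for r0 in range(0, acq.n_repetitions, 64):
            r1 = min(r0 + 64, acq.n_repetitions)
            block = out[r0:r1]
            block += rng.normal(0.0, sd, size=block.shape)
            block += 1j * rng.normal(0.0, sd, size=block.shape)
    return KSpaceSeries(out, t, acq.tr_ms, order)


# per-compartment perfusion used by the ASL emulator, chosen to track the
# cardiac modulation amplitudes (gray ~3x white, vessels strongest)
_DEFAULT_PERFUSION = {
    "background": 0.0, "white": 20.0, "gray": 60.0, "csf": 5.0,
    "aca_l": 100.0, "aca_r": 100.0, "mca_l": 100.0, "mca_r": 100.0,
    "pca_l": 100.0, "pca_r": 100.0, "sinus": 80.0,
}


def simulate_pcasl(
    phantom: PhantomTruth,
    n_pairs: int = 45,
    perfusion_scale: float = 1e-4,
    noise_sd: float = 0.01,
    seed: int = 0,
    perfusion: Mapping[str, float] | None = None,
):
    """Emulate a control/label ASL magnitude series with known perfusion.

    ``control = baseline + noise`` and
    ``label = baseline - perfusion_scale * f(x) + noise`` where ``f`` is a
    per-compartment perfusion value (default table above, correlated with the
    cardiac modulation amplitudes).  Kinetics are not simulated.

    Returns
    -------
    (PcaslSeries, ndarray)
        The paired series and the ground-truth perfusion image ``f``.
    """
    from .perfusion import PcaslSeries

    if n_pairs < 1:
        raise ConfigurationError("need at least one control/label pair")
    f = phantom._per_compartment_image(_merge(_DEFAULT_PERFUSION, perfusion or {}))
    base = phantom.baseline_image()
    rng = np.random.default_rng(seed)
    ref = float(base[phantom.brain_mask].mean())
    shape = (n_pairs,) + phantom.shape
    noise = lambda: rng.normal(0.0, noise_sd * ref, size=shape) if noise_sd > 0 else 0.0
    control = base[None] + noise()
    label = base[None] - perfusion_scale * f[None] + noise()
    series = PcaslSeries(
        control=control,
        label=label,
        label_duration_ms=1800.0,
        post_label_delay_ms=1800.0,
    )
    return series, f
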