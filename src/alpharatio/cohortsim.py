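"""Synthetic resting-state M/EEG cohort generation.

Emulates the statistical structure of eyes-open resting-state recordings from a
chronic-pain case-control study: an aperiodic 1/f background, a narrowband
alpha oscillation whose centre frequency differs between groups (slowed in
patients), stereotyped cardiac/ocular/powerline artifacts with reference
traces, and per-subject covariates (pain and depression scores).  Every
quantity is drawn from a seeded generator so that identical specs give
bit-identical output.

The generative model per channel ``c`` is::

    x_c(t) = aperiodic_c(t) + sum_k  w_kc * osc_k(t) + artifacts_c(t)

where ``aperiodic_c`` is independent Gaussian noise spectrally shaped to
``10**offset / f**exponent`` (flattened below 1 Hz so the variance is finite),
``osc_k`` is Gaussian noise shaped by a Gaussian spectral bump (centre
frequency, FWHM bandwidth, RMS amplitude) shared across channels, and ``w_kc``
is a nonnegative per-channel topography weight.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import InvalidArgumentError

__all__ = [
    "MIN_DURATION_S",
    "OscillatorSpec",
    "AperiodicSpec",
    "ArtifactConfig",
    "SubjectSpec",
    "GroupTemplate",
    "CohortSpec",
    "Recording",
    "RegionTimeSeries",
    "make_channel_meta",
    "make_region_meta",
    "default_alpha_topography",
    "hemisphere_mask",
    "simulate_subject",
    "simulate_regions",
    "draw_subject_specs",
    "simulate_cohort",
    "simulate_feature_matrix",
    "control_template",
    "patient_template",
]

#: Shortest recording the simulator will produce: two default Welch windows.
MIN_DURATION_S = 8.0

_FWHM_TO_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))


# ---------------------------------------------------------------------------
# Specs


@dataclass
class OscillatorSpec:
    """A narrowband stochastic oscillation.

    Parameters
    ----------
    center_freq : float
        Spectral peak location in Hz (e.g. 10.25 for a typical eyes-open
        alpha rhythm, 8.25/9.25 for slowed variants).
    bandwidth : float
        Full width at half maximum of the spectral bump, Hz.
    amplitude : float
        RMS amplitude of the oscillation time course (before topography
        weighting), in the same arbitrary units as the background.
    topography : ndarray or None
        Nonnegative per-channel (or per-region) weights.  ``None`` selects the
        default posterior-weighted profile at simulation time.
    """

    center_freq: float
    bandwidth: float = 2.0
    amplitude: float = 0.04
    topography: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.center_freq <= 0:
            raise InvalidArgumentError("center_freq must be > 0")
        if self.bandwidth <= 0:
            raise InvalidArgumentError("bandwidth must be > 0")
        if self.amplitude < 0:
            raise InvalidArgumentError("amplitude must be >= 0")
        if self.topography is not None:
            topo = np.asarray(self.topography, dtype=float)
            if topo.ndim != 1:
                raise InvalidArgumentError("topography must be a 1-D weight vector")
            if np.any(topo < 0):
                raise InvalidArgumentError("topography weights must be nonnegative")
            if not np.any(topo > 0):
                raise InvalidArgumentError("topography needs at least one positive weight")
            self.topography = topo


@dataclass
class AperiodicSpec:
    """1/f-like background: power density ~ ``10**offset / f**exponent``."""

    offset: float = 0.0
    exponent: float = 1.0

    def __post_init__(self) -> None:
        if self.exponent < 0:
            raise InvalidArgumentError("aperiodic exponent must be >= 0")


@dataclass
class ArtifactConfig:
    """Rates and amplitudes of the stereotyped artifact generators.

    Amplitudes are peak values on the strongest channel (topographies are
    max-normalised); rates of zero disable the corresponding artifact.
    """

    cardiac_rate: float = 60.0       # beats / min
    cardiac_amplitude: float = 0.3
    blink_rate: float = 12.0         # events / min
    blink_amplitude: float = 0.5
    line_freq: float = 50.0          # Hz
    line_amplitude: float = 0.05

    def __post_init__(self) -> None:
        if self.cardiac_rate < 0 or self.blink_rate < 0:
            raise InvalidArgumentError("artifact rates must be >= 0")
        if self.line_freq < 0:
            raise InvalidArgumentError("line_freq must be >= 0")

    @classmethod
    def none(cls) -> "ArtifactConfig":
        """Artifact-free configuration (all amplitudes zero)."""
        return cls(cardiac_amplitude=0.0, blink_amplitude=0.0, line_amplitude=0.0)


@dataclass
class SubjectSpec:
    """Complete generative description of one subject."""

    group: str
    oscillators: Sequence[OscillatorSpec] = ()
    aperiodic: AperiodicSpec = field(default_factory=AperiodicSpec)
    artifacts: ArtifactConfig = field(default_factory=ArtifactConfig)
    covariates: Mapping[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        self.oscillators = tuple(self.oscillators)
        self.covariates = dict(self.covariates)


@dataclass
class GroupTemplate:
    """Distribution over subject parameters for one group.

    ``peak_options`` lists alternative sets of oscillator centre frequencies
    (an empty tuple means "no clear alpha peak": the oscillator amplitude is
    zero); ``peak_probs`` are the mixture proportions over those options and
    must sum to one.  Per-subject centre frequencies are jittered by a normal
    deviation with SD ``peak_freq_sd``; amplitudes are lognormal around
    ``amplitude``; the aperiodic exponent is jittered with SD ``exponent_sd``.

    ``covariates`` maps a covariate name to a ``(mean, sd)`` pair; draws are
    truncated at zero.  ``covariate_slowing_corr`` couples a covariate to the
    subject's alpha slowing score (10.25 minus the slowest assigned peak, in
    Hz) with the given correlation; the default of 0 makes correlation
    analyses testable under the null.
    """

    peak_options: Sequence[Sequence[float]] = ((10.25,),)
    peak_probs: Sequence[float] = (1.0,)
    peak_freq_sd: float = 0.25
    amplitude: float = 0.04
    amplitude_sd_log: float = 0.2
    bandwidth: float = 2.0
    aperiodic: AperiodicSpec = field(default_factory=AperiodicSpec)
    exponent_sd: float = 0.1
    artifacts: ArtifactConfig = field(default_factory=ArtifactConfig)
    covariates: Mapping[str, tuple[float, float]] = field(default_factory=dict)
    covariate_slowing_corr: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.peak_options = tuple(tuple(float(f) for f in opt) for opt in self.peak_options)
        probs = np.asarray(self.peak_probs, dtype=float)
        if len(probs) != len(self.peak_options):
            raise InvalidArgumentError("peak_probs must match peak_options in length")
        if np.any(probs < 0) or abs(probs.sum() - 1.0) > 1e-9:
            raise InvalidArgumentError(
                f"peak mixture proportions must be nonnegative and sum to 1 (got sum={probs.sum()!r})"
            )
        self.peak_probs = tuple(float(p) for p in probs)


def control_template(**overrides) -> GroupTemplate:
    """Template for pain-free controls: a single ~10.25 Hz alpha peak."""
    defaults = dict(
        peak_options=((10.25,),),
        peak_probs=(1.0,),
        covariates={
            "pain_vas": (0.0, 0.0),
            "pain_duration": (0.0, 0.0),
            "depression_score": (1.0, 2.0),
        },
    )
    defaults.update(overrides)
    return GroupTemplate(**defaults)


def patient_template(**overrides) -> GroupTemplate:
    """Template for chronic-pain patients.

    The alpha peak mixture follows the observed contributions in a 21-patient
    FBSS cohort: 4 subjects with an 8.25 Hz peak, 11 with 9.25 Hz, 4 with both
    peaks and 2 with no clear alpha peak.
    """
    defaults = dict(
        peak_options=((8.25,), (9.25,), (8.25, 9.25), ()),
        peak_probs=(4 / 21, 11 / 21, 4 / 21, 2 / 21),
        covariates={
            "pain_vas": (5.0, 2.4),
            "pain_duration": (10.0, 9.0),
            "depression_score": (9.0, 4.0),
        },
    )
    defaults.update(overrides)
    return GroupTemplate(**defaults)


@dataclass
class CohortSpec:
    """Sizes, recording parameters and per-group templates for a cohort."""

    n_control: int = 25
    n_patient: int = 21
    control: GroupTemplate = field(default_factory=control_template)
    patient: GroupTemplate = field(default_factory=patient_template)
    duration: float = 300.0
    sampling_rate: float = 600.0
    n_channels: int = 64
    n_regions: int = 8
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_control < 2 or self.n_patient < 2:
            raise InvalidArgumentError("n_control and n_patient must each be >= 2")


# ---------------------------------------------------------------------------
# Containers


@dataclass
class Recording:
    """Multichannel time series with channel metadata and reference traces.

    ``data`` is ``(n_channels, n_samples)`` in arbitrary signal units.
    ``channel_meta`` has one row per channel with columns ``label``, ``x``,
    ``y`` (2-D layout position), ``hemisphere`` (``L``/``R``/``midline``) and
    ``region``.  ``reference_channels`` holds named artifact reference traces
    (e.g. ``cardiac``, ``ocular``).  ``annotations`` is a list of
    ``(start_s, end_s, kind)`` bad segments.
    """

    data: np.ndarray
    sampling_rate: float
    channel_meta: pd.DataFrame
    reference_channels: dict[str, np.ndarray] = field(default_factory=dict)
    annotations: list[tuple[float, float, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise InvalidArgumentError("data must be 2-D (channels x samples)")
        if self.sampling_rate <= 0:
            raise InvalidArgumentError("sampling_rate must be > 0")
        if len(self.channel_meta) != self.data.shape[0]:
            raise InvalidArgumentError("channel_meta rows must match data channels")
        for ref in self.reference_channels.values():
            if len(ref) != self.data.shape[1]:
                raise InvalidArgumentError("reference channels must match data length")
        dur = self.duration
        for start, end, _ in self.annotations:
            if not (0.0 <= start < end <= dur + 1.0 / self.sampling_rate):
                raise InvalidArgumentError(
                    f"annotation ({start}, {end}) outside recording [0, {dur:.3f}]"
                )

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.data.shape[1] / self.sampling_rate

    @property
    def signal_meta(self) -> pd.DataFrame:
        """Alias used by spectral code, which accepts recordings or region sets."""
        return self.channel_meta

    def with_data(self, data: np.ndarray) -> "Recording":
        return replace(self, data=np.asarray(data, dtype=float))


@dataclass
class RegionTimeSeries:
    """Per-region average source time series.

    ``region_meta`` has columns ``name``, ``hemisphere``, ``n_grid_points``
    and ``pair`` (homologous left/right pair id, -1 for unpaired).
    """

    data: np.ndarray
    sampling_rate: float
    region_meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise InvalidArgumentError("data must be 2-D (regions x samples)")
        if self.sampling_rate <= 0:
            raise InvalidArgumentError("sampling_rate must be > 0")
        if len(self.region_meta) != self.data.shape[0]:
            raise InvalidArgumentError("region_meta rows must match data regions")

    @property
    def n_regions(self) -> int:
        return self.data.shape[0]

    @property
    def signal_meta(self) -> pd.DataFrame:
        return self.region_meta

    def with_data(self, data: np.ndarray) -> "RegionTimeSeries":
        return replace(self, data=np.asarray(data, dtype=float))


# ---------------------------------------------------------------------------
# Layout / metadata helpers


def make_channel_meta(n_channels: int) -> pd.DataFrame:
    """Circular 2-D sensor layout with hemisphere and coarse region labels.

    Channels sit on a unit circle starting at the front midline and proceeding
    clockwise; hemisphere follows the sign of x.
    """
    idx = np.arange(n_channels)
    theta = 2.0 * np.pi * idx / n_channels
    x = np.sin(theta)
    y = np.cos(theta)
    hemi = np.where(x > 1e-9, "R", np.where(x < -1e-9, "L", "midline"))
    region = np.where(y > 0.38, "frontal", np.where(y < -0.38, "occipital", "temporal"))
    return pd.DataFrame(
        {
            "label": [f"MEG{i + 1:03d}" for i in idx],
            "x": x,
            "y": y,
            "hemisphere": hemi,
            "region": region,
        }
    )


def make_region_meta(n_regions: int, n_grid_points: int | Sequence[int] = 50) -> pd.DataFrame:
    """Homologous L/R region pairs; an odd trailing region is midline."""
    if np.isscalar(n_grid_points):
        sizes = np.full(n_regions, int(n_grid_points))
    else:
        sizes = np.asarray(n_grid_points, dtype=int)
        if len(sizes) != n_regions:
            raise InvalidArgumentError("n_grid_points must be scalar or length n_regions")
    names, hemis, pairs = [], [], []
    for i in range(n_regions):
        pair = i // 2
        if i == n_regions - 1 and n_regions % 2 == 1:
            names.append(f"region{pair + 1:02d}_M")
            hemis.append("midline")
            pairs.append(-1)
        else:
            side = "L" if i % 2 == 0 else "R"
            names.append(f"region{pair + 1:02d}_{side}")
            hemis.append(side)
            pairs.append(pair)
    return pd.DataFrame(
        {"name": names, "hemisphere": hemis, "n_grid_points": sizes, "pair": pairs}
    )


def default_alpha_topography(meta: pd.DataFrame) -> np.ndarray:
    """Posterior-weighted channel profile: all sensors see alpha, occipital most."""
    if "x" in meta.columns and "y" in meta.columns:
        x = meta["x"].to_numpy(dtype=float)
        y = meta["y"].to_numpy(dtype=float)
        return 0.4 + 0.6 * np.exp(-(x**2 + (y + 1.0) ** 2) / 0.8)
    return np.ones(len(meta))


def hemisphere_mask(meta: pd.DataFrame, hemisphere: str) -> np.ndarray:
    """Binary topography selecting one hemisphere (``L``/``R``/``midline``)."""
    return (meta["hemisphere"].to_numpy() == hemisphere).astype(float)


# ---------------------------------------------------------------------------
# Signal generation primitives


def _narrowband_noise(rng: np.random.Generator, n: int, fs: float, f0: float, bandwidth: float) -> np.ndarray:
    """Unit-RMS Gaussian noise with a Gaussian spectral bump (FWHM = bandwidth)."""
    white = rng.standard_normal(n)
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    sigma = bandwidth / _FWHM_TO_SIGMA
    shape = np.exp(-0.5 * ((freqs - f0) / sigma) ** 2)
    x = np.fft.irfft(np.fft.rfft(white) * shape, n)
    rms = math.sqrt(float(np.mean(x**2)))
    return x / rms if rms > 0 else x


def _aperiodic_noise(
    rng: np.random.Generator, n_channels: int, n: int, fs: float, spec: AperiodicSpec
) -> np.ndarray:
    """Independent per-channel noise with one-sided PSD (2/fs) * 10**offset / f**exponent.

    The density is flattened below 1 Hz so total variance stays finite; the
    analysis band starts well above that knee.
    """
    white = rng.standard_normal((n_channels, n))
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    f_eff = np.maximum(freqs, 1.0)
    gain = np.sqrt(10.0**spec.offset / f_eff**spec.exponent)
    gain[0] = 0.0
    return np.fft.irfft(np.fft.rfft(white, axis=1) * gain, n, axis=1)


def _ricker(fs: float, a: float = 0.015, half_width_s: float = 0.06) -> np.ndarray:
    """Mexican-hat waveform used as a stereotyped QRS-like cardiac shape."""
    t = np.arange(-half_width_s, half_width_s + 0.5 / fs, 1.0 / fs)
    return (1.0 - (t / a) ** 2) * np.exp(-(t**2) / (2.0 * a**2))


def _blink_waveform(fs: float, sigma_s: float = 0.08, half_width_s: float = 0.25) -> np.ndarray:
    t = np.arange(-half_width_s, half_width_s + 0.5 / fs, 1.0 / fs)
    return np.exp(-(t**2) / (2.0 * sigma_s**2))


def _event_train(n: int, fs: float, times_s: np.ndarray, waveform: np.ndarray) -> np.ndarray:
    """Sum of the waveform centred at each event time, length n."""
    out = np.zeros(n)
    half = len(waveform) // 2
    for t in times_s:
        centre = int(round(t * fs))
        lo, hi = centre - half, centre - half + len(waveform)
        wlo = max(0, -lo)
        whi = len(waveform) - max(0, hi - n)
        lo, hi = max(lo, 0), min(hi, n)
        if lo < hi:
            out[lo:hi] += waveform[wlo:whi]
    return out


def _cardiac_times(rng: np.random.Generator, duration: float, rate_bpm: float) -> np.ndarray:
    """Quasi-periodic beat times with 5% inter-beat jitter."""
    if rate_bpm <= 0:
        return np.array([])
    base = 60.0 / rate_bpm
    times = [float(rng.uniform(0.2, 0.2 + base))]
    while times[-1] < duration - 0.2:
        gap = base * max(0.5, 1.0 + 0.05 * rng.standard_normal())
        times.append(times[-1] + gap)
    return np.asarray(times[:-1]) if times[-1] >= duration - 0.2 else np.asarray(times)


def _poisson_times(
    rng: np.random.Generator, duration: float, rate_per_min: float, refractory: float = 1.0
) -> np.ndarray:
    if rate_per_min <= 0:
        return np.array([])
    mean_gap = 60.0 / rate_per_min
    times: list[float] = []
    t = float(rng.exponential(mean_gap))
    while t < duration - 0.3:
        times.append(t)
        t += refractory + float(rng.exponential(max(mean_gap - refractory, 1e-3)))
    return np.asarray(times)


# ---------------------------------------------------------------------------
# Simulation operations


def _simulate_signals(
    spec: SubjectSpec,
    duration: float,
    sampling_rate: float,
    meta: pd.DataFrame,
    with_artifacts: bool,
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Shared core for sensor- and region-level simulation."""
    if duration < MIN_DURATION_S:
        raise InvalidArgumentError(
            f"duration must be >= {MIN_DURATION_S} s (two Welch windows); got {duration}"
        )
    n_signals = len(meta)
    n = int(round(duration * sampling_rate))
    rng = np.random.default_rng(spec.seed)

    data = _aperiodic_noise(rng, n_signals, n, sampling_rate, spec.aperiodic)

    for osc in spec.oscillators:
        topo = osc.topography
        if topo is None:
            topo = default_alpha_topography(meta)
        topo = np.asarray(topo, dtype=float)
        if len(topo) != n_signals:
            raise InvalidArgumentError(
                f"topography length {len(topo)} does not match {n_signals} signals"
            )
        course = _narrowband_noise(rng, n, sampling_rate, osc.center_freq, osc.bandwidth)
        data += np.outer(topo, osc.amplitude * course)

    refs: dict[str, np.ndarray] = {}
    if with_artifacts:
        art = spec.artifacts
        # Cardiac: jittered quasi-periodic stereotyped waveform, fixed signed topography.
        beat_times = _cardiac_times(rng, duration, art.cardiac_rate)
        cardiac_topo = rng.standard_normal(n_signals)
        cardiac_topo /= max(np.abs(cardiac_topo).max(), 1e-12)
        cardiac = _event_train(n, sampling_rate, beat_times, _ricker(sampling_rate))
        if art.cardiac_amplitude > 0 and len(beat_times):
            data += np.outer(cardiac_topo, art.cardiac_amplitude * cardiac)
        refs["cardiac"] = cardiac + 0.01 * rng.standard_normal(n)

        # Ocular: slow positive transients, frontal topography.
        blink_times = _poisson_times(rng, duration, art.blink_rate)
        if "y" in meta.columns:
            blink_topo = np.exp(
                -(meta["x"].to_numpy() ** 2 + (meta["y"].to_numpy() - 1.0) ** 2) / 0.5
            )
        else:
            blink_topo = np.linspace(1.0, 0.1, n_signals)
        blink_topo = blink_topo / max(blink_topo.max(), 1e-12)
        blink = _event_train(n, sampling_rate, blink_times, _blink_waveform(sampling_rate))
        if art.blink_amplitude > 0 and len(blink_times):
            data += np.outer(blink_topo, art.blink_amplitude * blink)
        refs["ocular"] = blink + 0.01 * rng.standard_normal(n)

        # Powerline: common sinusoid with mildly varying channel gains.
        if art.line_amplitude > 0 and 0 < art.line_freq < sampling_rate / 2:
            phase = rng.uniform(0, 2 * np.pi)
            gains = rng.uniform(0.8, 1.2, n_signals)
            t = np.arange(n) / sampling_rate
            data += np.outer(gains, art.line_amplitude * np.sin(2 * np.pi * art.line_freq * t + phase))
    return data, refs


def simulate_subject(
    spec: SubjectSpec,
    duration: float = 300.0,
    sampling_rate: float = 600.0,
    n_channels: int = 64,
    channel_meta: pd.DataFrame | None = None,
) -> Recording:
    """Simulate one subject's sensor-level recording.

    Returns a :class:`Recording` whose data are the aperiodic background plus
    topography-weighted narrowband oscillations plus configured artifacts;
    clean cardiac/ocular reference traces are attached.  Identical
    ``(spec, duration, sampling_rate, n_channels)`` give identical output.
    """
    if n_channels < 2:
        raise InvalidArgumentError("n_channels must be >= 2")
    meta = channel_meta if channel_meta is not None else make_channel_meta(n_channels)
    data, refs = _simulate_signals(spec, duration, sampling_rate, meta, with_artifacts=True)
    return Recording(
        data=data,
        sampling_rate=sampling_rate,
        channel_meta=meta.reset_index(drop=True),
        reference_channels=refs,
    )


def simulate_regions(
    spec: SubjectSpec,
    n_regions: int = 8,
    duration: float = 300.0,
    sampling_rate: float = 600.0,
    region_meta: pd.DataFrame | None = None,
    with_artifacts: bool = False,
) -> RegionTimeSeries:
    """Simulate per-region average source time series for one subject.

    Stands in for the (out-of-scope) inverse solution: region traces follow
    the same generative model as sensor channels, with oscillator topographies
    defined over regions.  Artifacts are off by default at the region level
    (source reconstruction follows artifact cleaning in the emulated
    workflow).
    """
    if n_regions < 2:
        raise InvalidArgumentError("n_regions must be >= 2")
    meta = region_meta if region_meta is not None else make_region_meta(n_regions)
    # Region-level default topography is uniform, not posterior-weighted.
    osc = [
        o if o.topography is not None else replace(o, topography=np.ones(len(meta)))
        for o in spec.oscillators
    ]
    spec_r = replace(spec, oscillators=tuple(osc))
    data, _ = _simulate_signals(spec_r, duration, sampling_rate, meta, with_artifacts=with_artifacts)
    return RegionTimeSeries(data=data, sampling_rate=sampling_rate, region_meta=meta.reset_index(drop=True))


# ---------------------------------------------------------------------------
# Cohort-level draws


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float) -> float:
    return float(max(0.0, mean + sd * rng.standard_normal())) if sd > 0 else float(mean)


def _draw_subject(
    rng: np.random.Generator,
    template: GroupTemplate,
    group: str,
    seed: int,
) -> tuple[SubjectSpec, str]:
    """Draw one SubjectSpec from a group template.  Returns (spec, assignment label)."""
    opt_idx = int(rng.choice(len(template.peak_options), p=np.asarray(template.peak_probs)))
    option = template.peak_options[opt_idx]
    assignment = "+".join(f"{f:g}" for f in option) if option else "none"

    oscillators = []
    n_osc = len(option)
    for f0 in option:
        centre = max(2.0, f0 + template.peak_freq_sd * rng.standard_normal())
        amp = template.amplitude * math.exp(template.amplitude_sd_log * rng.standard_normal())
        if n_osc > 1:
            amp /= math.sqrt(n_osc)
        oscillators.append(
            OscillatorSpec(center_freq=centre, bandwidth=template.bandwidth, amplitude=amp)
        )

    exponent = max(0.0, template.aperiodic.exponent + template.exponent_sd * rng.standard_normal())
    aperiodic = AperiodicSpec(offset=template.aperiodic.offset, exponent=exponent)

    # Slowing score: how far the slowest assigned peak sits below 10.25 Hz.
    slowest = min((o.center_freq for o in oscillators), default=10.25)
    slowing_z = (10.25 - slowest) / max(template.peak_freq_sd, 1e-6)
    covariates: dict[str, float] = {}
    for name, (mean, sd) in template.covariates.items():
        rho = float(template.covariate_slowing_corr.get(name, 0.0))
        z = rho * slowing_z + math.sqrt(max(0.0, 1.0 - rho**2)) * rng.standard_normal()
        covariates[name] = float(max(0.0, mean + sd * z)) if sd > 0 else float(mean)

    spec = SubjectSpec(
        group=group,
        oscillators=oscillators,
        aperiodic=aperiodic,
        artifacts=template.artifacts,
        covariates=covariates,
        seed=seed,
    )
    return spec, assignment


def draw_subject_specs(cohort: CohortSpec) -> tuple[list[SubjectSpec], pd.DataFrame]:
    """Draw all subject specs and the aligned subject table for a cohort.

    The master seed fixes group assignments, per-subject parameters and the
    per-subject simulation seeds (stored in the table's ``seed`` column).
    """
    ss = np.random.SeedSequence(cohort.master_seed)
    rng = np.random.default_rng(ss.spawn(1)[0])
    n_total = cohort.n_control + cohort.n_patient
    child_seeds = [int(s) & 0x7FFFFFFF for s in ss.generate_state(n_total)]

    specs: list[SubjectSpec] = []
    rows: list[dict] = []
    for i in range(n_total):
        is_control = i < cohort.n_control
        group = "control" if is_control else "patient"
        template = cohort.control if is_control else cohort.patient
        spec, assignment = _draw_subject(rng, template, group, child_seeds[i])
        specs.append(spec)
        rows.append(
            {
                "subject_id": f"sub-{i + 1:03d}",
                "group": group,
                "seed": child_seeds[i],
                "peak_assignment": assignment,
                **spec.covariates,
            }
        )
    return specs, pd.DataFrame(rows)


def simulate_cohort(cohort: CohortSpec) -> tuple[list[Recording], pd.DataFrame]:
    """Simulate a full sensor-level cohort: recordings plus subject table."""
    specs, table = draw_subject_specs(cohort)
    recordings = [
        simulate_subject(
            spec,
            duration=cohort.duration,
            sampling_rate=cohort.sampling_rate,
            n_channels=cohort.n_channels,
        )
        for spec in specs
    ]
    return recordings, table


def simulate_feature_matrix(
    n_a: int,
    n_b: int,
    n_signals: int = 64,
    n_features: int = 7,
    effect_size: float = 1.5,
    effect_fraction: float = 0.0,
    seed: int | None = None,
    group_labels: tuple[str, str] = ("control", "patient"),
):
    """Feature-level surrogate cohort for calibrating the statistics layer.

    Draws a subjects x signals x features matrix of unit-variance Gaussian
    features (the generator's null template at the feature level).  A fraction
    ``effect_fraction`` of the signal x feature cells receives a mean shift of
    ``effect_size`` (Cohen's d) in group b.  Returns ``(feature_matrix,
    true_effect_mask)`` where the matrix is a
    :class:`~alpharatio.groupstats.FeatureMatrix`.
    """
    from .groupstats import FeatureMatrix  # deferred: groupstats does not import back

    rng = np.random.default_rng(seed)
    n = n_a + n_b
    values = rng.standard_normal((n, n_signals, n_features))
    mask = np.zeros((n_signals, n_features), dtype=bool)
    if effect_fraction > 0:
        m = n_signals * n_features
        k = int(round(effect_fraction * m))
        idx = rng.choice(m, size=k, replace=False)
        mask.flat[idx] = True
        values[n_a:] += effect_size * mask[None, :, :]
    feature_names = [f"feature_{j + 1}" for j in range(n_features)]
    if n_features == 7:
        from .spectral import FEATURE_NAMES

        feature_names = list(FEATURE_NAMES)
    table = pd.DataFrame(
        {
            "subject_id": [f"sub-{i + 1:03d}" for i in range(n)],
            "group": [group_labels[0]] * n_a + [group_labels[1]] * n_b,
        }
    )
    signal_meta = pd.DataFrame({"name": [f"signal{i + 1:03d}" for i in range(n_signals)]})
    fm = FeatureMatrix(
        values=values, feature_names=feature_names, subject_table=table, signal_meta=signal_meta
    )
    return fm, mask
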