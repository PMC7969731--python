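"""Synthetic multivoxel BOLD and behavioral data with known ground truth.

Raw fMRI for this paradigm is not publicly available, so every downstream
stage of the analysis is exercised on simulated data that reproduces the
experimental design: ten 300-s decoder-construction runs of orientation
trials, 5-min resting scans into which an orientation-pattern signal of
known sign and amplitude can be planted, the fixation color task's event
schedule, and a two-interval forced-choice observer that drives the
adaptive staircases.

Timing conventions: TR = 2 s; a decoder run is 6 s fixation + 18 trials of
(12 s stimulus + 4 s response) + 6 s fixation = 300 s = 150 volumes.  The
BOLD response to each 12-s stimulus is modeled as a boxcar delayed by 6 s,
which is exactly what the shift-and-average analysis assumes (the pipeline
never deconvolves an HRF, so neither does the generator).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .preprocess import VolumeSeries

__all__ = [
    "TuningMap",
    "DecoderScanDesign",
    "RestScanDesign",
    "ObserverModel",
    "FixationTaskSchedule",
    "make_tuning",
    "generate_decoder_scan",
    "generate_rest_scan",
    "generate_fixation_schedule",
    "simulate_observer_response",
]

ORIENTATION_A = "45"
ORIENTATION_B = "135"
ORIENTATIONS = (ORIENTATION_A, ORIENTATION_B)


@dataclass(frozen=True)
class TuningMap:
    """Per-voxel orientation tuning and noise model for one ROI.

    ``beta`` is the signed orientation-contrast amplitude in BOLD signal
    units: positive voxels respond more to orientation A (45°), negative
    ones to orientation B (135°).  Constructing from ``beta`` alone uses
    the antisymmetric model (response to A = +beta, to B = -beta);
    passing ``beta_a``/``beta_b`` instead gives each orientation its own
    response pattern, which is what cortical orientation maps look like
    (the two patterns are distinct, not mirror images) and what makes the
    template-similarity analysis able to distinguish suppression of one
    orientation from reactivation of the other.

    Noise is white Gaussian of SD ``sigma_noise`` per volume, optionally
    AR(1) in time; each run carries a linear drift with slope drawn from
    ``drift_slope_range``, and each (voxel, run) may contain at most one
    injected spike of ``spike_magnitude`` noise-SDs.  A spike inflates
    the within-run SD it is later measured against, so to trip the 10-SD
    filter at 150 volumes it must exceed about 17 nominal SDs; the
    default of 25 does so comfortably.
    """

    beta: np.ndarray | None = None
    beta_a: np.ndarray | None = None
    beta_b: np.ndarray | None = None
    baseline: float = 100.0
    sigma_noise: float = 1.0
    rho_ar1: float = 0.0
    drift_slope_range: tuple[float, float] = (-0.01, 0.01)
    spike_prob: float = 0.0
    spike_magnitude: float = 25.0

    def __post_init__(self) -> None:
        if self.beta is not None:
            if self.beta_a is not None or self.beta_b is not None:
                raise ValueError("pass either beta or (beta_a, beta_b), not both")
            beta = np.asarray(self.beta, dtype=float)
            beta_a, beta_b = beta, -beta
        else:
            if self.beta_a is None or self.beta_b is None:
                raise ValueError("pass either beta or both beta_a and beta_b")
            beta_a = np.asarray(self.beta_a, dtype=float)
            beta_b = np.asarray(self.beta_b, dtype=float)
            if beta_a.shape != beta_b.shape:
                raise ValueError("beta_a and beta_b must have the same shape")
        object.__setattr__(self, "beta_a", beta_a)
        object.__setattr__(self, "beta_b", beta_b)
        object.__setattr__(self, "beta", (beta_a - beta_b) / 2.0)
        if beta_a.ndim != 1 or beta_a.size < 2:
            raise ValueError("tuning must be 1-D with at least 2 voxels")
        if not self.sigma_noise > 0:
            raise ValueError("sigma_noise must be positive")
        if not 0.0 <= self.rho_ar1 < 1.0:
            raise ValueError("rho_ar1 must be in [0, 1)")
        if not 0.0 <= self.spike_prob <= 1.0:
            raise ValueError("spike_prob must be in [0, 1]")
        lo, hi = self.drift_slope_range
        if hi < lo:
            raise ValueError("drift_slope_range must be (low, high) with low <= high")

    @property
    def n_voxels(self) -> int:
        return self.beta_a.size

    def response(self, orientation: str) -> np.ndarray:
        """Per-voxel evoked response pattern for one orientation."""
        if orientation == ORIENTATION_A:
            return self.beta_a
        if orientation == ORIENTATION_B:
            return self.beta_b
        raise ValueError(f"unknown orientation {orientation!r}")

    def pattern_for(self, orientation: str) -> np.ndarray:
        """Unit-norm response pattern for one orientation."""
        v = self.response(orientation)
        norm = float(np.linalg.norm(v))
        return np.zeros_like(v) if norm == 0.0 else v / norm

    @property
    def pattern(self) -> np.ndarray:
        """Unit-norm orientation-contrast direction, unit(beta)."""
        norm = float(np.linalg.norm(self.beta))
        if norm == 0.0:
            return np.zeros_like(self.beta)
        return self.beta / norm


def make_tuning(
    n_voxels: int,
    n_informative: int,
    amplitude: float,
    seed: int,
    **kwargs,
) -> TuningMap:
    """Random tuning map with ``n_informative`` orientation-selective voxels.

    Each informative voxel prefers one orientation (chosen at random) and
    responds to it with ``amplitude``; the remaining voxels are untuned.
    The two orientations therefore activate disjoint voxel subsets, so
    their patterns are distinct rather than sign flips of each other, and
    the signed contrast beta is ±amplitude/2 on informative voxels.
    """
    if not 0 <= n_informative <= n_voxels:
        raise ValueError("need 0 <= n_informative <= n_voxels")
    rng = np.random.default_rng(seed)
    beta_a = np.zeros(n_voxels)
    beta_b = np.zeros(n_voxels)
    idx = rng.choice(n_voxels, size=n_informative, replace=False)
    prefers_a = rng.random(n_informative) < 0.5
    beta_a[idx[prefers_a]] = amplitude
    beta_b[idx[~prefers_a]] = amplitude
    return TuningMap(beta_a=beta_a, beta_b=beta_b, **kwargs)


@dataclass(frozen=True)
class DecoderScanDesign:
    """Timing of the decoder-construction scan (defaults match the study)."""

    tr_seconds: float = 2.0
    n_runs: int = 10
    trials_per_run: int = 18
    stim_seconds: float = 12.0
    response_seconds: float = 4.0
    fixation_seconds: float = 6.0
    hemodynamic_delay_seconds: float = 6.0

    def __post_init__(self) -> None:
        for name in ("tr_seconds", "stim_seconds"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.trials_per_run % 2 != 0:
            raise ValueError("trials_per_run must be even (balanced labels)")
        for name in (
            "stim_seconds",
            "response_seconds",
            "fixation_seconds",
            "hemodynamic_delay_seconds",
        ):
            if getattr(self, name) % self.tr_seconds != 0:
                raise ValueError(f"{name} must be a multiple of tr_seconds")

    @property
    def trial_seconds(self) -> float:
        return self.stim_seconds + self.response_seconds

    @property
    def run_seconds(self) -> float:
        return 2 * self.fixation_seconds + self.trials_per_run * self.trial_seconds

    @property
    def volumes_per_run(self) -> int:
        return int(round(self.run_seconds / self.tr_seconds))

    @property
    def stim_volumes(self) -> int:
        return int(round(self.stim_seconds / self.tr_seconds))

    def trial_onsets(self) -> np.ndarray:
        """Trial onsets in seconds within a run."""
        return self.fixation_seconds + self.trial_seconds * np.arange(
            self.trials_per_run
        )


@dataclass(frozen=True)
class RestScanDesign:
    """A 5-min resting scan with a plantable orientation-pattern signal.

    ``planted_amplitude`` (alpha) multiplies the unit tuning pattern:
    positive plants reactivation of orientation A, negative suppression
    (i.e. the pattern of orientation B), zero is the null.  Because the
    analysis z-scores every voxel within the scan, a pattern that is
    constant for the whole scan is removed exactly by the mean
    subtraction; a recoverable trace must therefore wax and wane.  The
    default ``modulation='epoch'`` switches the pattern on and off in
    epochs of ``epoch_volumes`` volumes with probability ``duty_cycle``,
    emulating a sustained but fluctuating reactivation trace.
    ``modulation='constant'`` implements the literal tonic signal, which
    is useful as an explicit demonstration that the published pipeline is
    blind to it.
    """

    duration_seconds: float = 300.0
    tr_seconds: float = 2.0
    planted_amplitude: float = 0.0
    target_orientation: str = ORIENTATION_A
    modulation: str = "epoch"
    duty_cycle: float = 0.75
    epoch_volumes: int = 6
    epoch_offset_volumes: int = 3

    def __post_init__(self) -> None:
        if self.duration_seconds <= 0 or self.tr_seconds <= 0:
            raise ValueError("durations must be positive")
        if self.duration_seconds % self.tr_seconds != 0:
            raise ValueError("duration_seconds must be divisible by tr_seconds")
        if self.modulation not in ("epoch", "constant"):
            raise ValueError("modulation must be 'epoch' or 'constant'")
        if not 0.0 <= self.duty_cycle <= 1.0:
            raise ValueError("duty_cycle must be in [0, 1]")
        if self.epoch_volumes < 1 or self.epoch_offset_volumes < 0:
            raise ValueError("invalid epoch geometry")

    @property
    def n_volumes(self) -> int:
        return int(round(self.duration_seconds / self.tr_seconds))


@dataclass(frozen=True)
class ObserverModel:
    """A 2IFC observer with a logistic psychometric function in log S/N.

    ``threshold_snr`` is the S/N ratio at which the observer performs at
    ``target_accuracy`` (default 0.707, the convergence point of a
    2-down 1-up staircase).  Performance is bounded between the 2IFC
    guess rate and 1 - lapse_rate and is monotonically non-decreasing
    in S/N.
    """

    threshold_snr: float = 0.05
    slope: float = 10.0
    lapse_rate: float = 0.02
    guess_rate: float = 0.5
    target_accuracy: float = 0.707

    def __post_init__(self) -> None:
        if not 0 < self.threshold_snr <= 1:
            raise ValueError("threshold_snr must be in (0, 1]")
        if self.slope <= 0:
            raise ValueError("slope must be positive")
        if not 0.0 <= self.lapse_rate <= 0.1:
            raise ValueError("lapse_rate must be in [0, 0.1]")
        upper = 1.0 - self.lapse_rate
        if not self.guess_rate < self.target_accuracy < upper:
            raise ValueError("target_accuracy must lie between guess and 1 - lapse")

    def p_correct(self, snr) -> np.ndarray | float:
        """P(correct) at the given S/N ratio(s) in [0, 1]."""
        snr = np.asarray(snr, dtype=float)
        if np.any((snr < 0) | (snr > 1)):
            raise ValueError("snr must be in [0, 1]")
        span = 1.0 - self.guess_rate - self.lapse_rate
        # place the logistic midpoint so that p(threshold) = target accuracy
        frac = (self.target_accuracy - self.guess_rate) / span
        offset = math.log(frac / (1.0 - frac)) / self.slope
        with np.errstate(divide="ignore"):
            x = np.where(snr > 0, np.log10(np.maximum(snr, 1e-300)), -np.inf)
        z = self.slope * (x - (math.log10(self.threshold_snr) - offset))
        p = self.guess_rate + span / (1.0 + np.exp(-z))
        p = np.where(snr == 0.0, self.guess_rate, p)
        return float(p) if p.ndim == 0 else p

    def with_threshold(self, threshold_snr: float) -> "ObserverModel":
        return replace(self, threshold_snr=threshold_snr)


@dataclass(frozen=True)
class FixationTaskSchedule:
    """Onsets of the fixation-dot color-change events within one scan."""

    event_onsets: np.ndarray
    event_duration: float = 1.5
    isi_bounds: tuple[float, float] = (0.5, 0.8)
    isi_mean: float = 0.67
    scan_duration: float = 300.0

    @property
    def n_events(self) -> int:
        return int(np.asarray(self.event_onsets).size)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "onset_s": np.asarray(self.event_onsets, dtype=float),
                "duration_s": self.event_duration,
            }
        )


# ---------------------------------------------------------------------------
# noise machinery


def _noise(rng: np.random.Generator, shape, tuning: TuningMap) -> np.ndarray:
    """White or stationary AR(1) Gaussian noise of SD sigma_noise."""
    eps = rng.standard_normal(shape)
    rho = tuning.rho_ar1
    if rho > 0.0:
        out = np.empty_like(eps)
        out[0] = eps[0]
        scale = math.sqrt(1.0 - rho * rho)
        for t in range(1, shape[0]):
            out[t] = rho * out[t - 1] + scale * eps[t]
        eps = out
    return tuning.sigma_noise * eps


def _drift(rng: np.random.Generator, n_volumes: int, tuning: TuningMap) -> np.ndarray:
    lo, hi = tuning.drift_slope_range
    slope = rng.uniform(lo, hi)
    return slope * np.arange(n_volumes)[:, None]


def _spikes(
    rng: np.random.Generator, data: np.ndarray, tuning: TuningMap
) -> np.ndarray:
    """Inject at most one spike per voxel into one run's matrix (in place)."""
    if tuning.spike_prob == 0.0:
        return data
    n_volumes, n_voxels = data.shape
    hit = rng.random(n_voxels) < tuning.spike_prob
    when = rng.integers(0, n_volumes, size=n_voxels)
    sign = rng.choice([-1.0, 1.0], size=n_voxels)
    amp = tuning.spike_magnitude * tuning.sigma_noise
    for v in np.flatnonzero(hit):
        data[when[v], v] += sign[v] * amp
    return data


# ---------------------------------------------------------------------------
# generators


def generate_decoder_scan(
    design: DecoderScanDesign, tuning: TuningMap, seed: int
) -> tuple[list[VolumeSeries], pd.DataFrame]:
    """Simulate the decoder-construction scan.

    Returns the runs (each ``volumes x voxels``) and a trial table with
    columns (run, trial, onset_s, orientation).  Within every run exactly
    half of the trials carry each orientation, in seeded pseudorandom
    order.  The stimulus response is a boxcar of ±beta occupying the 6
    volumes starting ``hemodynamic_delay_seconds`` after trial onset.
    """
    rng = np.random.default_rng(seed)
    n_vol = design.volumes_per_run
    delay_vol = int(round(design.hemodynamic_delay_seconds / design.tr_seconds))
    onsets = design.trial_onsets()
    half = design.trials_per_run // 2

    runs: list[VolumeSeries] = []
    rows = []
    for run in range(design.n_runs):
        labels = np.array([ORIENTATION_A] * half + [ORIENTATION_B] * half)
        rng.shuffle(labels)
        data = np.full((n_vol, tuning.n_voxels), float(tuning.baseline))
        for trial, (onset, lab) in enumerate(zip(onsets, labels)):
            start = int(round(onset / design.tr_seconds)) + delay_vol
            stop = start + design.stim_volumes
            if stop > n_vol:
                raise ValueError("trial response window exceeds run length")
            data[start:stop] += tuning.response(lab)
            rows.append(
                {
                    "run": run,
                    "trial": trial,
                    "onset_s": float(onset),
                    "orientation": lab,
                }
            )
        data += _drift(rng, n_vol, tuning)
        data += _noise(rng, data.shape, tuning)
        _spikes(rng, data, tuning)
        runs.append(
            VolumeSeries(
                data=data,
                tr_seconds=design.tr_seconds,
                run_id=run,
                scan_role="decoder",
            )
        )
    return runs, pd.DataFrame(rows)


def rest_signal_timecourse(
    design: RestScanDesign, rng: np.random.Generator
) -> np.ndarray:
    """Per-volume 0/1 gate of the planted pattern (all ones when constant)."""
    n = design.n_volumes
    if design.modulation == "constant":
        return np.ones(n)
    gate = np.zeros(n)
    # leading partial epoch, then full epochs of epoch_volumes
    edges = [0, design.epoch_offset_volumes] if design.epoch_offset_volumes else [0]
    t = edges[-1]
    while t < n:
        t += design.epoch_volumes
        edges.append(min(t, n))
    for lo, hi in zip(edges[:-1], edges[1:]):
        if rng.random() < design.duty_cycle:
            gate[lo:hi] = 1.0
    return gate


def generate_rest_scan(
    design: RestScanDesign,
    tuning: TuningMap,
    seed: int,
    scan_role: str = "pre",
    voxel_ids: np.ndarray | None = None,
    gate_seed: int | None = None,
) -> VolumeSeries:
    """Simulate one 5-min resting scan.

    The planted signal is the unit response pattern of the design's
    target orientation scaled by ``planted_amplitude`` (negative =
    anti-pattern, i.e. suppression of the target) and gated by the
    epochal time course (see :class:`RestScanDesign`), on top of
    baseline, linear drift and noise; spikes are injected as configured.
    ``gate_seed`` decouples the gate from the noise stream so that a
    signal planted in several ROIs of the same scan can wax and wane
    coherently across them (one trace per brain state, not per ROI).
    """
    rng = np.random.default_rng(seed)
    n_vol = design.n_volumes
    gate_rng = rng if gate_seed is None else np.random.default_rng(gate_seed)
    gate = rest_signal_timecourse(design, gate_rng)
    u = tuning.pattern_for(design.target_orientation)
    data = np.full((n_vol, tuning.n_voxels), float(tuning.baseline))
    data += design.planted_amplitude * gate[:, None] * u[None, :]
    data += _drift(rng, n_vol, tuning)
    data += _noise(rng, data.shape, tuning)
    _spikes(rng, data, tuning)
    return VolumeSeries(
        data=data,
        tr_seconds=design.tr_seconds,
        run_id=0,
        scan_role=scan_role,
        voxel_ids=voxel_ids,
    )


# Two-point ISI mixture on {0.5, 0.8} s with mean exactly 0.67 s.  A
# continuous uniform on [0.5, 0.8] would have mean 0.65, which contradicts
# the design's stated mean interval of 0.67 s; the two-point mixture is the
# simplest distribution on the stated support with the stated mean.
ISI_VALUES = (0.5, 0.8)
ISI_WEIGHTS = (13.0 / 30.0, 17.0 / 30.0)


def generate_fixation_schedule(
    scan_duration: float,
    seed: int,
    event_duration: float = 1.5,
    isi_values: tuple[float, ...] = ISI_VALUES,
    isi_weights: tuple[float, ...] = ISI_WEIGHTS,
) -> FixationTaskSchedule:
    """Pack fixation color-change events into one scan.

    Events are scheduled sequentially from t = 0: each occupies
    ``event_duration`` seconds and is followed by an ISI drawn from the
    configured distribution; the last event must end before the scan does.
    With the defaults the expected cycle is 1.5 + 0.67 = 2.17 s, i.e. about
    138 events per 5-min scan.
    """
    if scan_duration <= 0:
        raise ValueError("scan_duration must be positive")
    rng = np.random.default_rng(seed)
    onsets = []
    t = 0.0
    while t + event_duration <= scan_duration:
        onsets.append(t)
        t += event_duration + rng.choice(isi_values, p=isi_weights)
    mean_isi = float(np.dot(isi_values, isi_weights))
    return FixationTaskSchedule(
        event_onsets=np.asarray(onsets),
        event_duration=event_duration,
        isi_bounds=(min(isi_values), max(isi_values)),
        isi_mean=mean_isi,
        scan_duration=scan_duration,
    )


def simulate_observer_response(
    observer: ObserverModel, snr: float, seed: int | np.random.Generator
) -> bool:
    """One Bernoulli 2IFC trial: True = correct response."""
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    p = observer.p_correct(snr)
    return bool(rng.random() < p)
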