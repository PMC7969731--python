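"""BOLD preprocessing chain: shift, spike filter, detrend, z-score, average.

The chain mirrors the published analysis exactly and in a fixed order:

1. shift the signal by the hemodynamic delay (6 s = 3 volumes at TR 2 s),
2. remove voxels with spikes > 10 within-run SDs in any decoder run,
3. remove a per-voxel linear trend within each run,
4. z-score each voxel within each run,
5. average 6-volume windows into samples (one per trial for the decoder
   scan; consecutive non-overlapping windows for the resting scans).

Each operation records itself in the series' ``history``; applying a stage
before an earlier stage of the chain raises :class:`PipelineOrderError`.
Re-applying the same stage is allowed (detrending and z-scoring are
idempotent), only going backwards is not.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "VolumeSeries",
    "SampleMatrix",
    "PipelineOrderError",
    "hemodynamic_shift",
    "detect_spike_voxels",
    "drop_voxels",
    "detrend_linear",
    "zscore_per_run",
    "extract_trial_samples",
    "extract_rest_windows",
    "preprocess_decoder_runs",
    "preprocess_rest_scan",
]

logger = logging.getLogger(__name__)

# chain stages in mandatory order
_STAGE_RANK = {"shift": 0, "spike_mask": 1, "detrend": 2, "zscore": 3}


class PipelineOrderError(RuntimeError):
    """Raised when preprocessing stages are applied out of order."""


@dataclass(frozen=True)
class VolumeSeries:
    """One run's BOLD matrix, volumes x voxels, plus timing metadata."""

    data: np.ndarray
    tr_seconds: float
    run_id: int = 0
    scan_role: str = "decoder"
    voxel_ids: np.ndarray | None = None
    history: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        object.__setattr__(self, "data", data)
        if data.ndim != 2:
            raise ValueError("data must be 2-D (volumes x voxels)")
        if data.shape[0] < 12:
            raise ValueError("need at least 12 volumes")
        if np.isnan(data).any():
            raise ValueError("data must not contain missing values")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        if self.voxel_ids is None:
            object.__setattr__(self, "voxel_ids", np.arange(data.shape[1]))
        else:
            ids = np.asarray(self.voxel_ids)
            if ids.size != data.shape[1]:
                raise ValueError("voxel_ids length must match voxel count")
            object.__setattr__(self, "voxel_ids", ids)

    @property
    def n_volumes(self) -> int:
        return self.data.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.data.shape[1]

    def _with(self, data: np.ndarray, stage: str, **kw) -> "VolumeSeries":
        return replace(self, data=data, history=self.history + (stage,), **kw)

    def _check_stage(self, stage: str) -> None:
        rank = _STAGE_RANK[stage]
        done = [_STAGE_RANK[s] for s in self.history if s in _STAGE_RANK]
        if done and max(done) > rank:
            raise PipelineOrderError(
                f"cannot apply '{stage}' after later stages {self.history!r}; "
                "required order is shift -> spike_mask -> detrend -> zscore"
            )


@dataclass(frozen=True)
class SampleMatrix:
    """Trial- or window-averaged samples x voxels.

    ``labels`` holds the orientation of each sample for decoder scans and
    is None for (unlabeled) resting windows.  ``provenance`` records which
    volume indices of the preprocessed series were averaged into each
    sample.
    """

    data: np.ndarray
    labels: np.ndarray | None
    run_ids: np.ndarray
    voxel_ids: np.ndarray
    provenance: tuple[tuple[int, ...], ...] = ()

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        object.__setattr__(self, "data", data)
        if data.ndim != 2:
            raise ValueError("data must be 2-D (samples x voxels)")
        if self.labels is not None:
            labels = np.asarray(self.labels)
            if labels.size != data.shape[0]:
                raise ValueError("labels length must match sample count")
            object.__setattr__(self, "labels", labels)
        run_ids = np.asarray(self.run_ids)
        if run_ids.size != data.shape[0]:
            raise ValueError("run_ids length must match sample count")
        object.__setattr__(self, "run_ids", run_ids)
        object.__setattr__(self, "voxel_ids", np.asarray(self.voxel_ids))

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.data.shape[1]


# ---------------------------------------------------------------------------
# chain operations


def hemodynamic_shift(series: VolumeSeries, shift_seconds: float = 6.0) -> VolumeSeries:
    """Advance the event-to-volume mapping by the hemodynamic delay.

    Implemented as an index remap (no interpolation): the shifted series
    at volume t is the raw series at volume t + shift/TR, so an event at
    onset t seconds reads the volumes acquired from t + shift onward.  The
    trailing shift/TR volumes have no shifted coverage and are dropped.
    """
    series._check_stage("shift")
    if shift_seconds % series.tr_seconds != 0:
        raise ValueError(
            f"shift of {shift_seconds} s is not a multiple of TR = "
            f"{series.tr_seconds} s"
        )
    k = int(round(shift_seconds / series.tr_seconds))
    data = series.data[k:] if k else series.data
    return series._with(np.array(data, copy=True), "shift")


def detect_spike_voxels(
    runs: list[VolumeSeries], sd_threshold: float = 10.0
) -> np.ndarray:
    """Voxel removal mask: True where a voxel spikes in ANY run.

    A voxel is flagged if, within any single run, some volume deviates
    from that voxel's within-run mean by more than ``sd_threshold``
    within-run (sample) SDs.  Zero-variance voxels are never flagged by
    this rule (their deviations are 0, which is not > 0).
    """
    if not runs:
        raise ValueError("need at least one run")
    n_vox = runs[0].n_voxels
    removal = np.zeros(n_vox, dtype=bool)
    for run in runs:
        if run.n_voxels != n_vox:
            raise ValueError("all runs must share the voxel set")
        mean = run.data.mean(axis=0)
        sd = run.data.std(axis=0, ddof=1)
        dev = np.abs(run.data - mean)
        removal |= (dev > sd_threshold * sd).any(axis=0)
    return removal


def drop_voxels(series: VolumeSeries, removal_mask: np.ndarray) -> VolumeSeries:
    """Remove the flagged voxels (inherits the decoder-run spike mask)."""
    series._check_stage("spike_mask")
    removal_mask = np.asarray(removal_mask, dtype=bool)
    if removal_mask.size != series.n_voxels:
        raise ValueError("mask length must match voxel count")
    keep = ~removal_mask
    return series._with(
        np.array(series.data[:, keep], copy=True),
        "spike_mask",
        voxel_ids=series.voxel_ids[keep],
    )


def detrend_linear(series: VolumeSeries) -> VolumeSeries:
    """Remove each voxel's ordinary-least-squares linear trend in time."""
    series._check_stage("detrend")
    n = series.n_volumes
    if n < 3:
        raise ValueError("need at least 3 volumes to detrend")
    t = np.arange(n, dtype=float)
    t_c = t - t.mean()
    y = series.data
    slope = t_c @ (y - y.mean(axis=0)) / (t_c @ t_c)
    fitted = y.mean(axis=0) + np.outer(t_c, slope)
    return series._with(y - fitted, "detrend")


def zscore_per_run(series: VolumeSeries) -> VolumeSeries:
    """Z-score each voxel within the run (sample SD, denominator n - 1).

    Zero-variance voxels are set to all zeros and logged rather than
    dropped, so that voxel indices stay aligned with the decoder's; the
    sparse decoder prunes uninformative voxels itself.
    """
    series._check_stage("zscore")
    if series.n_volumes < 2:
        raise ValueError("need at least 2 volumes to z-score")
    mean = series.data.mean(axis=0)
    sd = series.data.std(axis=0, ddof=1)
    flat = sd == 0.0
    if flat.any():
        logger.warning(
            "z-score: %d zero-variance voxel(s) set to zeros (run %s)",
            int(flat.sum()),
            series.run_id,
        )
    safe_sd = np.where(flat, 1.0, sd)
    z = (series.data - mean) / safe_sd
    z[:, flat] = 0.0
    return series._with(z, "zscore")


_FULL_CHAIN = ("shift", "spike_mask", "detrend", "zscore")


def _require_chain(series: VolumeSeries, required: tuple[str, ...]) -> None:
    seen = [s for s in series.history if s in _STAGE_RANK]
    it = iter(seen)
    for stage in required:
        if not any(s == stage for s in it):
            raise PipelineOrderError(
                f"series history {series.history!r} is missing stage "
                f"'{stage}'; apply the chain {required} in order first"
            )


def extract_trial_samples(
    runs: list[VolumeSeries],
    labels: pd.DataFrame,
    design,
) -> SampleMatrix:
    """One sample per trial: the mean of the trial's 6 stimulus volumes.

    ``runs`` must already have gone through the full chain; ``labels`` is
    the trial table (run, trial, onset_s, orientation) produced alongside
    the simulated scan; ``design`` supplies the timing.  After the 6-s
    shift a trial at onset t reads the shifted volumes starting at t/TR.
    """
    for run in runs:
        _require_chain(run, _FULL_CHAIN)
    by_run = {run.run_id: run for run in runs}
    stim_vol = design.stim_volumes
    rows, labs, run_ids, prov = [], [], [], []
    for _, row in labels.sort_values(["run", "trial"]).iterrows():
        run = by_run[row["run"]]
        start = int(round(row["onset_s"] / run.tr_seconds))
        stop = start + stim_vol
        if stop > run.n_volumes:
            raise ValueError(
                f"trial window [{start}, {stop}) exceeds shifted run length "
                f"{run.n_volumes}"
            )
        rows.append(run.data[start:stop].mean(axis=0))
        labs.append(row["orientation"])
        run_ids.append(row["run"])
        prov.append(tuple(range(start, stop)))
    return SampleMatrix(
        data=np.array(rows),
        labels=np.array(labs),
        run_ids=np.array(run_ids),
        voxel_ids=runs[0].voxel_ids,
        provenance=tuple(prov),
    )


def extract_rest_windows(
    scan: VolumeSeries, window_volumes: int = 6, phase: int = 0
) -> SampleMatrix:
    """Average consecutive non-overlapping windows of a resting scan.

    Windows start at the first usable volume (plus ``phase`` volumes) and
    the trailing partial window is discarded.  A 150-volume scan loses 3
    volumes to the hemodynamic shift, leaving 147, of which 24 windows
    (144 volumes) are used and 3 discarded.
    """
    _require_chain(scan, _FULL_CHAIN)
    usable = scan.n_volumes - phase
    n_windows = usable // window_volumes
    if n_windows < 1:
        raise ValueError(
            f"scan has {usable} usable volumes, fewer than one "
            f"{window_volumes}-volume window"
        )
    rows, prov = [], []
    for w in range(n_windows):
        start = phase + w * window_volumes
        stop = start + window_volumes
        rows.append(scan.data[start:stop].mean(axis=0))
        prov.append(tuple(range(start, stop)))
    logger.debug(
        "rest windows: %d windows, %d trailing volume(s) discarded",
        n_windows,
        usable - n_windows * window_volumes,
    )
    return SampleMatrix(
        data=np.array(rows),
        labels=None,
        run_ids=np.full(n_windows, scan.run_id),
        voxel_ids=scan.voxel_ids,
        provenance=tuple(prov),
    )


def preprocess_decoder_runs(
    runs: list[VolumeSeries],
    labels: pd.DataFrame,
    design,
    sd_threshold: float = 10.0,
) -> tuple[SampleMatrix, np.ndarray]:
    """Run the full chain on the decoder scan; returns (samples, spike mask)."""
    shifted = [hemodynamic_shift(r, design.hemodynamic_delay_seconds) for r in runs]
    mask = detect_spike_voxels(shifted, sd_threshold=sd_threshold)
    cleaned = [zscore_per_run(detrend_linear(drop_voxels(r, mask))) for r in shifted]
    return extract_trial_samples(cleaned, labels, design), mask


def preprocess_rest_scan(
    scan: VolumeSeries,
    spike_mask: np.ndarray,
    shift_seconds: float = 6.0,
    window_volumes: int = 6,
) -> SampleMatrix:
    """Full chain on one resting scan, inheriting the decoder spike mask."""
    s = hemodynamic_shift(scan, shift_seconds)
    s = zscore_per_run(detrend_linear(drop_voxels(s, spike_mask)))
    return extract_rest_windows(s, window_volumes=window_volumes)
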