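"""End-to-end cohort runner: simulate -> preprocess -> decode -> statistics.

:func:`run_cohort` simulates a cohort of subjects through the full study
design and analysis:

* day-1 decoder-construction scan per subject (all ROIs), preprocessing,
  and one sparse-logistic decoder per ROI (V1, V2, V3, and V1-V3
  combined);
* day-4 resting scans: two pre scans (no planted signal), and post1/post2
  scan pairs after exposure to the novel and to the familiar orientation.
  The study conditions plant reactivation of the novel orientation in V1
  during post1 (positive amplitude) and suppression of the familiar
  orientation across V1-V3 during post1 (negative amplitude); post2 and
  pre carry no signal.  Exposure order is counterbalanced: exactly half
  of the subjects meet the novel orientation first;
* behavioral tests: three 2-down 1-up staircase blocks per orientation
  before and after training, giving each subject's threshold S/N ratios
  and performance improvement.  Subjects who learn more receive
  proportionally deeper planted suppression, which is the association the
  median-split analysis looks for;
* the cohort statistics battery mirroring the study's inferential
  analyses (repeated-measures ANOVAs with sphericity handling, post-hoc
  t tests, quadratic trend, sign-consistency binomial tests, Dixon's
  outlier check, and the median-split comparison).

Everything is a pure function of (config, seed): rerunning with the same
arguments reproduces the report bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import behavior as bh
from . import decoder as dec
from . import preprocess as pp
from . import rest as rst
from . import stats as st
from . import synthetic as syn
from .synthetic import ORIENTATION_A, ORIENTATION_B

__all__ = ["StudyConfig", "CohortReport", "run_cohort", "cohort_signature"]

ROIS = ("V1", "V2", "V3")
COMBINED = "V1-V3"
_ROI_ID_STRIDE = 10_000


@dataclass(frozen=True)
class StudyConfig:
    """Study conditions for a simulated cohort (defaults match the design)."""

    n_subjects: int = 12
    roi_voxels: dict = field(
        default_factory=lambda: {"V1": 24, "V2": 20, "V3": 16}
    )
    informative_fraction: float = 0.5
    tuning_amplitude: float = 0.25
    sigma_noise: float = 1.0
    spike_prob: float = 0.005
    rho_ar1: float = 0.0
    # planted rest-scan effects (amplitudes are positive magnitudes)
    reactivation_amplitude: float = 2.5
    suppression_amplitude: float = 2.5
    duty_cycle: float = 0.75
    rest_modulation: str = "epoch"
    # behavioral simulation
    observer_threshold: float = 0.05
    observer_threshold_log10_sd: float = 0.12
    learning_mean: float = 0.30
    learning_sd: float = 0.08
    couple_suppression_to_learning: bool = True
    # decoder hyperparameters
    decoder_kwargs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("need at least one subject")
        if self.n_subjects % 2 and self.n_subjects > 1:
            raise ValueError(
                "n_subjects must be even so exposure order can be counterbalanced"
            )
        if not 0 < self.informative_fraction <= 1:
            raise ValueError("informative_fraction must be in (0, 1]")


@dataclass(frozen=True)
class CohortReport:
    """Per-subject scores plus the cohort statistics tables."""

    scores: pd.DataFrame
    behavior: pd.DataFrame
    stats: dict
    config: StudyConfig
    seed: int

    def pivot(self, condition: str, roi: str, value: str = "probability") -> pd.DataFrame:
        """subjects x (pre, post1, post2) table of one measure."""
        sel = self.scores[
            (self.scores.condition == condition) & (self.scores.roi == roi)
        ]
        return sel.pivot(index="subject", columns="scan", values=value)[
            ["pre", "post1", "post2"]
        ]


def _seed_ints(ss: np.random.SeedSequence, n: int) -> list[int]:
    return [int(x) for x in ss.generate_state(n) % (2**31)]


def _subset(samples: pp.SampleMatrix, lo: int, hi: int) -> pp.SampleMatrix:
    sel = (samples.voxel_ids >= lo) & (samples.voxel_ids < hi)
    return pp.SampleMatrix(
        data=samples.data[:, sel],
        labels=samples.labels,
        run_ids=samples.run_ids,
        voxel_ids=samples.voxel_ids[sel],
    )


def _simulate_subject(config: StudyConfig, subject: int, ss: np.random.SeedSequence,
                      novel_first: bool) -> tuple[list[dict], dict]:
    rng = np.random.default_rng(ss)
    seeds = iter(_seed_ints(ss.spawn(1)[0], 64))

    familiar = rng.choice([ORIENTATION_A, ORIENTATION_B])
    novel = ORIENTATION_B if familiar == ORIENTATION_A else ORIENTATION_A

    # ---- behavioral thresholds and learning ------------------------------
    thr0 = config.observer_threshold * 10 ** (
        rng.normal(0.0, config.observer_threshold_log10_sd)
    )
    thr0 = float(np.clip(thr0, 0.015, 0.3))
    true_improvement = float(
        np.clip(rng.normal(config.learning_mean, config.learning_sd), 0.05, 0.6)
    )
    observer_pre = syn.ObserverModel(threshold_snr=thr0)
    observer_post = observer_pre.with_threshold(thr0 * (1.0 - true_improvement))

    sc_cfg = bh.StaircaseConfig()
    improvements = {}
    for ori in (familiar, novel):
        pre_blocks = [
            bh.run_staircase(sc_cfg, observer_pre, next(seeds)) for _ in range(3)
        ]
        post_blocks = [
            bh.run_staircase(sc_cfg, observer_post, next(seeds)) for _ in range(3)
        ]
        improvements[ori] = bh.performance_improvement(pre_blocks, post_blocks)

    # ---- tuning and the decoder-construction scan ------------------------
    tunings, offsets = {}, {}
    for i, roi in enumerate(ROIS):
        nv = config.roi_voxels[roi]
        tunings[roi] = syn.make_tuning(
            nv,
            max(2, int(round(nv * config.informative_fraction))),
            config.tuning_amplitude,
            next(seeds),
            sigma_noise=config.sigma_noise,
            spike_prob=config.spike_prob,
            rho_ar1=config.rho_ar1,
        )
        offsets[roi] = i * _ROI_ID_STRIDE
    full_tuning = syn.TuningMap(
        beta_a=np.concatenate([tunings[r].beta_a for r in ROIS]),
        beta_b=np.concatenate([tunings[r].beta_b for r in ROIS]),
        sigma_noise=config.sigma_noise,
        spike_prob=config.spike_prob,
        rho_ar1=config.rho_ar1,
    )
    design = syn.DecoderScanDesign()
    runs, labels = syn.generate_decoder_scan(design, full_tuning, next(seeds))
    global_ids = np.concatenate(
        [offsets[r] + np.arange(config.roi_voxels[r]) for r in ROIS]
    )
    runs = [replace(r, voxel_ids=global_ids) for r in runs]
    samples_all, spike_mask = pp.preprocess_decoder_runs(runs, labels, design)

    roi_trials = {
        roi: _subset(samples_all, offsets[roi], offsets[roi] + _ROI_ID_STRIDE)
        for roi in ROIS
    }
    roi_trials[COMBINED] = dec.combine_rois([roi_trials[r] for r in ROIS])
    models = {
        roi: dec.fit(roi_trials[roi], **config.decoder_kwargs)
        for roi in roi_trials
    }
    templates = {roi: rst.build_templates(roi_trials[roi]) for roi in roi_trials}

    # ---- resting scans ----------------------------------------------------
    # planted amplitudes per (scan, roi); suppression depth scales with the
    # subject's true learning when so configured
    supp = config.suppression_amplitude
    if config.couple_suppression_to_learning and config.learning_mean > 0:
        supp *= float(np.clip(true_improvement / config.learning_mean, 0.25, 2.0))
    scan_specs = {
        "pre1": (0.0, novel, ()),
        "pre2": (0.0, novel, ()),
        "novel_post1": (config.reactivation_amplitude, novel, ("V1",)),
        "novel_post2": (0.0, novel, ()),
        "familiar_post1": (-supp, familiar, ROIS),
        "familiar_post2": (0.0, familiar, ()),
    }

    windows: dict[str, dict[str, pp.SampleMatrix]] = {}
    for scan_name, (amp, target, planted_rois) in scan_specs.items():
        # one gate per scan: the planted trace waxes and wanes coherently
        # across the ROIs it is planted in (a brain state, not a per-ROI one)
        gate_seed = next(seeds)
        per_roi = {}
        for roi in ROIS:
            rd = syn.RestScanDesign(
                planted_amplitude=amp if roi in planted_rois else 0.0,
                target_orientation=target,
                modulation=config.rest_modulation,
                duty_cycle=config.duty_cycle,
            )
            lo = offsets[roi]
            ids = lo + np.arange(config.roi_voxels[roi])
            per_roi[roi] = syn.generate_rest_scan(
                rd,
                tunings[roi],
                next(seeds),
                scan_role=scan_name,
                voxel_ids=ids,
                gate_seed=gate_seed,
            )
        windows[scan_name] = per_roi

    # preprocess with the decoder-run spike mask, per ROI, then combine
    roi_slices = {}
    start = 0
    for roi in ROIS:
        nv = config.roi_voxels[roi]
        roi_slices[roi] = slice(start, start + nv)
        start += nv
    rest_windows: dict[str, dict[str, pp.SampleMatrix]] = {}
    for scan_name, per_roi in windows.items():
        w = {
            roi: pp.preprocess_rest_scan(per_roi[roi], spike_mask[roi_slices[roi]])
            for roi in ROIS
        }
        w[COMBINED] = dec.combine_rois([w[r] for r in ROIS])
        rest_windows[scan_name] = w

    # ---- scores -----------------------------------------------------------
    rows = []
    for condition, target in (("novel", novel), ("familiar", familiar)):
        scan_map = {
            "pre": ("pre1", "pre2"),
            "post1": (f"{condition}_post1",),
            "post2": (f"{condition}_post2",),
        }
        for roi in (*ROIS, COMBINED):
            for scan_label, scan_names in scan_map.items():
                decs = [
                    rst.scan_probability(
                        models[roi],
                        rest_windows[s][roi],
                        target,
                        scan_role=scan_label,
                        roi=roi,
                    )
                    for s in scan_names
                ]
                prob = rst.combine_scan_scores(decs)
                sims = [
                    rst.similarity_timecourse(
                        templates[roi], rest_windows[s][roi], scan_role=scan_label,
                        roi=roi,
                    )
                    for s in scan_names
                ]
                sim_target = float(np.mean([s.mean_correlation(target) for s in sims]))
                other = ORIENTATION_B if target == ORIENTATION_A else ORIENTATION_A
                sim_other = float(np.mean([s.mean_correlation(other) for s in sims]))
                rows.append(
                    {
                        "subject": subject,
                        "condition": condition,
                        "roi": roi,
                        "scan": scan_label,
                        "target": target,
                        "probability": prob,
                        "similarity_target": sim_target,
                        "similarity_other": sim_other,
                        "n_windows": int(sum(d.n_windows for d in decs)),
                    }
                )

    behav = {
        "subject": subject,
        "familiar_orientation": familiar,
        "novel_first": bool(novel_first),
        "true_improvement": true_improvement,
        "improvement_familiar": improvements[familiar].improvement,
        "improvement_novel": improvements[novel].improvement,
        "threshold_pre_familiar": improvements[familiar].threshold_pre,
        "threshold_post_familiar": improvements[familiar].threshold_post,
    }
    return rows, behav


def run_cohort(config: StudyConfig, seed: int, compute_stats: bool = True) -> CohortReport:
    """Simulate and analyze a full cohort; deterministic in (config, seed)."""
    root = np.random.SeedSequence(seed)
    order_rng = np.random.default_rng(root.spawn(1)[0])
    n = config.n_subjects
    novel_first = np.zeros(n, dtype=bool)
    novel_first[order_rng.permutation(n)[: n // 2]] = True
    if n == 1:
        novel_first[0] = bool(order_rng.integers(2))

    subject_seeds = root.spawn(n + 1)[1:]
    all_rows, behav_rows = [], []
    for s in range(n):
        rows, behav = _simulate_subject(config, s, subject_seeds[s], novel_first[s])
        all_rows.extend(rows)
        behav_rows.append(behav)
    scores = pd.DataFrame(all_rows)
    behavior = pd.DataFrame(behav_rows)

    stats = (
        cohort_statistics(scores, behavior)
        if compute_stats and n >= 3
        else {"note": "cohort too small for inferential statistics"}
    )
    return CohortReport(
        scores=scores, behavior=behavior, stats=stats, config=config, seed=seed
    )


# ---------------------------------------------------------------------------
# the statistics battery


def _pivot(scores: pd.DataFrame, condition: str, roi: str, value: str) -> np.ndarray:
    sel = scores[(scores.condition == condition) & (scores.roi == roi)]
    wide = sel.pivot(index="subject", columns="scan", values=value)
    return wide[["pre", "post1", "post2"]].to_numpy()


def _time_by_region(scores: pd.DataFrame, condition: str, value: str) -> np.ndarray:
    """subjects x time(pre,post1,post2) x region(V1,V2,V3) array."""
    mats = [_pivot(scores, condition, roi, value) for roi in ROIS]
    return np.stack(mats, axis=2)


def cohort_statistics(scores: pd.DataFrame, behavior: pd.DataFrame) -> dict:
    """The study's inferential battery on a cohort's scores."""
    out: dict = {}

    # --- novel exposure: reactivation ------------------------------------
    y = _time_by_region(scores, "novel", "probability")
    out["novel_time_by_region"] = st.rm_anova_two_way(y, ("time", "region"))
    out["novel_time_within"] = {
        roi: st.rm_anova_one_way(_pivot(scores, "novel", roi, "probability"))
        for roi in ROIS
    }
    v1 = _pivot(scores, "novel", "V1", "probability")
    out["novel_v1_vs_chance"] = {
        scan: st.one_sample_t(v1[:, i], 0.5)
        for i, scan in enumerate(("pre", "post1", "post2"))
    }
    out["novel_v1_pre_vs_post1"] = st.paired_t(v1[:, 0], v1[:, 1])
    out["novel_v1_pre_vs_post2"] = st.paired_t(v1[:, 0], v1[:, 2])
    out["novel_v1_quadratic_trend"] = st.polynomial_trend_contrast(v1, order=2)
    out["novel_v1_sign_consistency"] = st.binomial_test_two_sided(
        int(np.sum(v1[:, 1] > v1[:, 0])), v1.shape[0]
    )
    v2_post1 = _pivot(scores, "novel", "V2", "probability")[:, 1]
    out["novel_v2_post1_dixon"] = st.dixon_q_test(v2_post1)

    # --- familiar exposure: suppression ----------------------------------
    y = _time_by_region(scores, "familiar", "probability")
    out["familiar_time_by_region"] = st.rm_anova_two_way(y, ("time", "region"))
    out["familiar_pre_vs_post1"] = {
        roi: st.paired_t(
            _pivot(scores, "familiar", roi, "probability")[:, 0],
            _pivot(scores, "familiar", roi, "probability")[:, 1],
        )
        for roi in ROIS
    }
    pooled = y.mean(axis=2)  # region-averaged V1-V3 scores
    out["familiar_pooled_pre_vs_post1"] = st.paired_t(pooled[:, 0], pooled[:, 1])
    out["familiar_sign_consistency"] = {
        roi: st.binomial_test_two_sided(
            int(
                np.sum(
                    _pivot(scores, "familiar", roi, "probability")[:, 1]
                    < _pivot(scores, "familiar", roi, "probability")[:, 0]
                )
            ),
            y.shape[0],
        )
        for roi in ("V2", "V3")
    }

    # --- pattern similarity ------------------------------------------------
    out["familiar_similarity_target"] = st.rm_anova_two_way(
        _time_by_region(scores, "familiar", "similarity_target"), ("time", "region")
    )
    out["familiar_similarity_other"] = st.rm_anova_two_way(
        _time_by_region(scores, "familiar", "similarity_other"), ("time", "region")
    )

    # --- direct comparison of the two exposures ---------------------------
    post1 = np.stack(
        [
            np.stack(
                [_pivot(scores, cond, roi, "probability")[:, 1] for roi in ROIS],
                axis=1,
            )
            for cond in ("novel", "familiar")
        ],
        axis=1,
    )  # subjects x stimulus type x region
    out["post1_type_by_region"] = st.rm_anova_two_way(post1, ("stimulus", "region"))

    # --- median splits on learning ----------------------------------------
    comb = scores[(scores.condition == "familiar") & (scores.roi == COMBINED)]
    supp_idx = (
        comb[comb.scan == "post1"].set_index("subject")["probability"].sort_index()
    )
    improv_fam = behavior.set_index("subject")["improvement_familiar"].sort_index()
    improv_nov = behavior.set_index("subject")["improvement_novel"].sort_index()
    out["suppression_by_learning_split"] = st.median_split_compare(
        supp_idx.to_numpy(), improv_fam.to_numpy()
    )
    out["suppression_by_novel_learning_split"] = st.median_split_compare(
        supp_idx.to_numpy(), improv_nov.to_numpy()
    )

    # --- exposure order ----------------------------------------------------
    novel_first = behavior.sort_values("subject")["novel_first"].to_numpy()
    v1_post1 = _pivot(scores, "novel", "V1", "probability")[:, 1]
    if 2 <= novel_first.sum() <= len(novel_first) - 2:
        lev = st.levene_test(v1_post1[novel_first], v1_post1[~novel_first])
        out["novel_v1_post1_by_order"] = st.independent_t(
            v1_post1[novel_first], v1_post1[~novel_first], equal_var=lev.p >= 0.05
        )
    return out


# ---------------------------------------------------------------------------
# qualitative signatures


def cohort_signature(
    report: CohortReport, prob_band: float = 0.05, sim_band: float = 0.03
) -> dict:
    """Does the cohort show the qualitative reactivation/suppression pattern?

    Reactivation (novel exposure, V1): post1 probability above chance and
    above pre; post2 back within ``prob_band`` of pre.  Suppression
    (familiar exposure, V1-V3 region mean): post1 below chance and below
    pre; post2 back within the band; and the similarity to the untouched
    (novel) orientation's template changed by less than ``sim_band``.
    All checks are on cohort means.
    """
    v1 = report.pivot("novel", "V1").to_numpy()
    fam = np.stack(
        [report.pivot("familiar", roi).to_numpy() for roi in ROIS], axis=2
    ).mean(axis=2)
    sim_other = report.pivot("familiar", COMBINED, "similarity_other").to_numpy()
    sim_target = report.pivot("familiar", COMBINED, "similarity_target").to_numpy()

    checks = {
        "reactivation_post1_above_chance": v1[:, 1].mean() > 0.5,
        "reactivation_post1_above_pre": v1[:, 1].mean() > v1[:, 0].mean(),
        "reactivation_post2_near_pre": abs(v1[:, 2].mean() - v1[:, 0].mean())
        < prob_band,
        "suppression_post1_below_chance": fam[:, 1].mean() < 0.5,
        "suppression_post1_below_pre": fam[:, 1].mean() < fam[:, 0].mean(),
        "suppression_post2_near_pre": abs(fam[:, 2].mean() - fam[:, 0].mean())
        < prob_band,
        "suppression_lowers_target_similarity": sim_target[:, 1].mean()
        < sim_target[:, 0].mean(),
        "untouched_similarity_unchanged": abs(
            sim_other[:, 1].mean() - sim_other[:, 0].mean()
        )
        < sim_band,
    }
    checks["all"] = all(checks.values())
    return checks
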