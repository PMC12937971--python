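"""Simulation-based validation studies for the whole pipeline.

The clinical recordings behind the device are not redistributable, so the
package validates its signal-processing and modelling claims on data it
can generate itself.  Three studies, each run over a grid of seeds under
the default study conditions (cohorts of 200 subjects, three repeats per
subject):

* ``qc_confusion_study`` scores the eyelid-reference filter against the
  simulator's ground-truth interference mask (window-level sensitivity
  and specificity, see :func:`corneafluor.qc.confusion_counts`);
* ``hybrid_mare_study`` measures the hybrid model's held-out mean
  absolute relative error on full pipeline runs;
* ``mlr_recovery_study`` fits the linear model on interference-free,
  attenuation-free cohorts and compares the recovered calibration slope
  and intercept with the generating values (slope ``1/gain``, intercept
  ``-baseline/gain``).
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from . import optics, qc
from .estimator import fit_mlr
from .pipeline import PipelineConfig, run_pipeline
from .simulate import CohortConfig, RecordingConfig, generate_cohort, simulate_recording

__all__ = [
    "qc_confusion_study",
    "hybrid_mare_study",
    "mlr_recovery_study",
]


def qc_confusion_study(
    seeds: Sequence[int],
    cohort: CohortConfig = CohortConfig(),
    recording: RecordingConfig = RecordingConfig(),
    qc_cfg: qc.QcConfig = qc.QcConfig(),
    pigment_conc: float = 0.002,
    path_length: float = 1.0,
) -> dict:
    """Pooled window-level sensitivity/specificity of the trend filter."""
    totals = {"tp": 0, "fp": 0, "tn": 0, "fn": 0}
    for seed in seeds:
        profiles, _ = generate_cohort(dataclasses.replace(cohort, seed=seed))
        rcfg = dataclasses.replace(recording, seed=seed + 1)
        masks, truths = [], []
        for profile in profiles:
            attenuation = optics.subject_transmittance(
                profile.pigment_class,
                profile.skin_tone,
                pigment_conc=pigment_conc,
                path_length=path_length,
            )
            for k in range(rcfg.n_repeats):
                rec = simulate_recording(profile, rcfg, attenuation, repeat_index=k)
                masks.append(qc.qc_recording(rec, qc_cfg))
                truths.append(rec.truth_interference_mask)
        counts = qc.confusion_counts(masks, truths)
        for key in totals:
            totals[key] += counts[key]
    sensitivity = totals["tp"] / max(totals["tp"] + totals["fn"], 1)
    specificity = totals["tn"] / max(totals["tn"] + totals["fp"], 1)
    return {
        "sensitivity": sensitivity,
        "specificity": specificity,
        "n_windows": sum(totals.values()),
        **totals,
    }


def hybrid_mare_study(
    seeds: Sequence[int], config: PipelineConfig = PipelineConfig()
) -> dict:
    """Held-out hybrid MARE (percent) per seed over full pipeline runs."""
    mares = []
    for seed in seeds:
        result = run_pipeline(dataclasses.replace(config, global_seed=seed))
        mares.append(result.evaluation["hybrid"]["mare_percent"])
    return {
        "per_seed": mares,
        "mean": float(np.mean(mares)),
        "max": float(np.max(mares)),
        "n_test_per_seed": int(
            round(config.cohort.n_subjects * config.test_size)
        ),
    }


def mlr_recovery_study(
    seeds: Sequence[int],
    cohort: CohortConfig = CohortConfig(),
    recording: RecordingConfig = RecordingConfig(),
    qc_cfg: qc.QcConfig = qc.QcConfig(),
) -> dict:
    """Relative recovery error of the linear calibration coefficients.

    Uses interference-free recordings at unit attenuation so the
    generating relation is exactly affine: serum ~ intensity with slope
    ``1/gain`` and intercept ``-baseline/gain`` (up to assay noise).
    """
    rcfg_clean = dataclasses.replace(recording, interference_rate=0.0)
    slope_true = 1.0 / recording.gain
    intercept_true = -recording.baseline / recording.gain
    slope_errors, intercept_errors = [], []
    for seed in seeds:
        profiles, table = generate_cohort(dataclasses.replace(cohort, seed=seed))
        rcfg = dataclasses.replace(rcfg_clean, seed=seed + 1)
        intensities = []
        for profile in profiles:
            recs = [
                simulate_recording(profile, rcfg, 1.0, repeat_index=k)
                for k in range(rcfg.n_repeats)
            ]
            masks = [qc.qc_recording(r, qc_cfg) for r in recs]
            summary = qc.summarize_valid(recs, masks, qc_cfg)
            intensities.append(summary.corrected_intensity)
        beta = fit_mlr(np.asarray(intensities), table["serum_age"].to_numpy())
        slope_errors.append(abs(beta[1] - slope_true) / abs(slope_true))
        intercept_errors.append(abs(beta[0] - intercept_true) / abs(intercept_true))
    return {
        "slope_true": slope_true,
        "intercept_true": intercept_true,
        "slope_rel_error_max": float(np.max(slope_errors)),
        "intercept_rel_error_max": float(np.max(intercept_errors)),
        "slope_rel_error_mean": float(np.mean(slope_errors)),
        "intercept_rel_error_mean": float(np.mean(intercept_errors)),
        "n_seeds": len(list(seeds)),
    }
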