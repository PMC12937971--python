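"""End-to-end pipeline: simulate -> QC -> fit -> agreement, plus the
laser-exposure safety validator.

``run_pipeline`` composes the whole desk-scale analysis: generate a
cohort, simulate repeated two-channel recordings per subject (pigment
attenuation from the optics model), reject interference windows with the
eyelid-reference filter, assemble per-subject features, fit the hybrid
MLR/SVR estimator on a training split and score held-out agreement with
the serum reference.  Every artifact is stamped with the resolved
configuration hash and seed; identical configuration reproduces identical
outputs.

The safety validator enforces the device's 365 nm exposure limits:
single-exposure dose below 3.9 mJ/cm^2, duration below 10 s, beam spot
diameter above 7 mm (all strict inequalities).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import optics, qc
from .agreement import AgreementReport, PairedMeasurements, agreement_report
from .estimator import HybridAGERegressor, HybridModelDocument, evaluate_models
from .exceptions import DomainError, StageError
from .simulate import (
    CohortConfig,
    RawRecording,
    RecordingConfig,
    SubjectProfile,
    generate_cohort,
    simulate_recording,
)

__all__ = [
    "ExposureSettings",
    "ExposureCheck",
    "validate_exposure",
    "PipelineConfig",
    "PipelineResult",
    "run_pipeline",
    "assemble_features",
]

CONFIG_SCHEMA_VERSION = "1.0"

#: Strict single-exposure safety limits for the 365 nm source.
DOSE_LIMIT_MJ_CM2 = 3.9
DURATION_LIMIT_S = 10.0
SPOT_DIAMETER_MIN_MM = 7.0

FEATURE_COLUMNS = ("corrected_intensity", "eyelid_reference", "valid_fraction", "bmi")


@dataclass(frozen=True)
class ExposureSettings:
    """Planned UV exposure; dose (mJ/cm^2) = irradiance (mW/cm^2) x duration (s)."""

    irradiance: float  # mW/cm^2
    duration: float  # s
    spot_diameter: float  # mm

    def __post_init__(self) -> None:
        if self.irradiance <= 0 or self.duration <= 0 or self.spot_diameter <= 0:
            raise DomainError("irradiance, duration and spot_diameter must be > 0")

    @property
    def dose(self) -> float:
        return self.irradiance * self.duration


@dataclass(frozen=True)
class ExposureCheck:
    passed: bool
    dose: float
    violations: tuple


def validate_exposure(settings: ExposureSettings) -> ExposureCheck:
    """Check settings against the strict exposure limits.

    Passes iff dose < 3.9 mJ/cm^2, duration < 10 s and spot diameter
    > 7 mm; failures list every violated limit.
    """
    violations = []
    if not settings.dose < DOSE_LIMIT_MJ_CM2:
        violations.append(
            f"dose {settings.dose:g} mJ/cm^2 not below {DOSE_LIMIT_MJ_CM2} mJ/cm^2"
        )
    if not settings.duration < DURATION_LIMIT_S:
        violations.append(
            f"duration {settings.duration:g} s not below {DURATION_LIMIT_S:g} s"
        )
    if not settings.spot_diameter > SPOT_DIAMETER_MIN_MM:
        violations.append(
            f"spot diameter {settings.spot_diameter:g} mm not above "
            f"{SPOT_DIAMETER_MIN_MM:g} mm"
        )
    return ExposureCheck(not violations, settings.dose, tuple(violations))


@dataclass(frozen=True)
class PipelineConfig:
    """Fully serializable configuration of one pipeline run."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    recording: RecordingConfig = field(default_factory=RecordingConfig)
    qc: qc.QcConfig = field(default_factory=qc.QcConfig)
    w_mlr: float = 0.7
    w_svr: float = 0.3
    svr_C: float = 10.0
    svr_gamma: float = 0.1
    svr_epsilon: float = 0.01
    variance_floor: float = 1e-8
    min_abs_corr: float = 0.3
    test_size: float = 0.3
    pigment_conc: float = 0.002  # g/100 mL, per-subject iris loading
    path_length: float = 1.0  # cm
    global_seed: int = 0
    schema_version: str = CONFIG_SCHEMA_VERSION

    def resolved(self) -> "PipelineConfig":
        """Propagate the global seed into the stage configs."""
        return dataclasses.replace(
            self,
            cohort=dataclasses.replace(self.cohort, seed=self.global_seed),
            recording=dataclasses.replace(
                self.recording, seed=self.global_seed + 1
            ),
        )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, payload: dict) -> "PipelineConfig":
        from .exceptions import SchemaVersionError

        payload = dict(payload)
        version = payload.pop("schema_version", CONFIG_SCHEMA_VERSION)
        if str(version).split(".")[0] != CONFIG_SCHEMA_VERSION.split(".")[0]:
            raise SchemaVersionError(f"unsupported config schema version {version!r}")
        kwargs = {}
        if "cohort" in payload:
            kwargs["cohort"] = CohortConfig(**payload.pop("cohort"))
        if "recording" in payload:
            kwargs["recording"] = RecordingConfig(**payload.pop("recording"))
        if "qc" in payload:
            kwargs["qc"] = qc.QcConfig(**payload.pop("qc"))
        kwargs.update(payload)
        return cls(schema_version=str(version), **kwargs)

    def config_hash(self) -> str:
        canonical = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canonical.encode("utf8")).hexdigest()[:16]


@dataclass
class PipelineResult:
    config: PipelineConfig
    config_hash: str
    cohort_table: pd.DataFrame
    measurements: pd.DataFrame
    features: pd.DataFrame
    model: HybridModelDocument
    evaluation: dict
    agreement: AgreementReport


def _simulate_subject(
    profile: SubjectProfile, config: PipelineConfig
) -> list[RawRecording]:
    attenuation = optics.subject_transmittance(
        profile.pigment_class,
        profile.skin_tone,
        pigment_conc=config.pigment_conc,
        path_length=config.path_length,
    )
    return [
        simulate_recording(profile, config.recording, attenuation, repeat_index=k)
        for k in range(config.recording.n_repeats)
    ]


def assemble_features(
    measurements: pd.DataFrame, cohort_table: pd.DataFrame
) -> pd.DataFrame:
    """Join corrected measurements with subject covariates.

    Keeps usable subjects only; output columns are ``subject_id``, the
    model features (:data:`FEATURE_COLUMNS`) and ``serum_age``.
    """
    merged = measurements.merge(
        cohort_table[["subject_id", "bmi", "serum_age"]], on="subject_id"
    )
    merged = merged[merged["usable"]].reset_index(drop=True)
    return merged[["subject_id", *FEATURE_COLUMNS, "serum_age"]]


def run_pipeline(
    config: PipelineConfig = PipelineConfig(),
    out_dir: Optional[Path] = None,
) -> PipelineResult:
    """Execute simulate -> QC -> fit -> agreement; optionally write artifacts.

    Raises :class:`StageError` naming the failing stage on any error.
    Rerunning with an identical configuration reproduces identical
    artifacts byte for byte.
    """
    config = config.resolved()
    cfg_hash = config.config_hash()

    try:
        profiles, cohort_table = generate_cohort(config.cohort)
    except Exception as exc:
        raise StageError("simulate", exc) from exc

    try:
        rows = []
        for profile in profiles:
            recordings = _simulate_subject(profile, config)
            masks = [qc.qc_recording(rec, config.qc) for rec in recordings]
            summary = qc.summarize_valid(recordings, masks, config.qc)
            rows.append(
                {
                    "subject_id": summary.subject_id,
                    "corrected_intensity": summary.corrected_intensity,
                    "eyelid_reference": summary.eyelid_reference,
                    "valid_fraction": summary.valid_fraction,
                    "n_repeats_used": summary.n_repeats_used,
                    "usable": summary.usable,
                }
            )
        measurements = pd.DataFrame(rows)
    except Exception as exc:
        raise StageError("qc", exc) from exc

    try:
        features = assemble_features(measurements, cohort_table)
        X = features[list(FEATURE_COLUMNS)]
        y = features["serum_age"].to_numpy()
        estimator = HybridAGERegressor(
            w_mlr=config.w_mlr,
            w_svr=config.w_svr,
            C=config.svr_C,
            gamma=config.svr_gamma,
            epsilon=config.svr_epsilon,
            variance_floor=config.variance_floor,
            min_abs_corr=config.min_abs_corr,
        )
        evaluation = evaluate_models(
            X,
            y,
            feature_names=list(FEATURE_COLUMNS),
            test_size=config.test_size,
            seed=config.global_seed,
            estimator=estimator,
        )
        model_doc = estimator.to_document()
    except Exception as exc:
        raise StageError("fit", exc) from exc

    try:
        # held-out agreement between device predictions and serum reference
        from sklearn.model_selection import train_test_split

        idx = np.arange(len(features))
        _, idx_te = train_test_split(
            idx, test_size=config.test_size, random_state=config.global_seed
        )
        predicted = estimator.predict(X.iloc[idx_te])
        pairs = PairedMeasurements(
            reference=y[idx_te],
            test=predicted,
            labels=tuple(features["subject_id"].iloc[idx_te]),
        )
        report = agreement_report(pairs)
    except Exception as exc:
        raise StageError("agreement", exc) from exc

    result = PipelineResult(
        config=config,
        config_hash=cfg_hash,
        cohort_table=cohort_table,
        measurements=measurements,
        features=features,
        model=model_doc,
        evaluation=evaluation,
        agreement=report,
    )
    if out_dir is not None:
        try:
            _write_artifacts(result, Path(out_dir))
        except Exception as exc:
            raise StageError("write", exc) from exc
    return result


def _write_artifacts(result: PipelineResult, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    stamp = {
        "schema_version": CONFIG_SCHEMA_VERSION,
        "config_hash": result.config_hash,
        "seed": result.config.global_seed,
        "config": result.config.to_dict(),
    }
    (out_dir / "config.json").write_text(json.dumps(stamp, indent=2, sort_keys=True))
    result.cohort_table.to_csv(out_dir / "cohort.csv", index=False)
    result.measurements.to_csv(out_dir / "measurements.csv", index=False)
    (out_dir / "model.json").write_text(result.model.to_json())
    (out_dir / "evaluation.json").write_text(
        json.dumps(result.evaluation, indent=2, sort_keys=True)
    )
    (out_dir / "agreement.json").write_text(result.agreement.to_json())
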