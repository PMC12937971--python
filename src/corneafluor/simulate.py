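"""Synthetic cohorts and two-channel fluorescence recordings.

The generator emulates the statistical structure the downstream analysis
assumes rather than device electronics:

* true corneal AGE concentration drawn in the physiological 2-7 ug/mL
  envelope, shifted upward by a dietary high-AGE propensity score;
* BMI positively coupled to the same diet score, so that BMI carries
  indirect information about AGE burden;
* a serum ELISA reference equal to the true concentration corrupted by
  multiplicative lognormal assay noise at a configurable CV;
* recordings in which the corneal channel carries the concentration signal
  (affine in concentration, scaled by a pigment transmittance factor) plus
  a slow illumination drift shared with the eyelid channel, and episodic
  ambient/reflection interference that drives the corneal channel
  *against* the shared drift -- the signature the eyelid-reference quality
  filter looks for.

Each interference episode adds a transient that anti-tracks the local
drift (factor ``interference_tracking``) plus a linear ramp of amplitude
``interference_amplitude`` whose slope sign opposes the concurrent eyelid
trend.  A per-sample boolean truth mask (simulator-only ground truth)
records contaminated samples so filter sensitivity and specificity can be
scored exactly.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, DomainError

__all__ = [
    "PIGMENT_CLASSES",
    "SKIN_TONES",
    "SubjectProfile",
    "CohortConfig",
    "RecordingConfig",
    "RawRecording",
    "generate_cohort",
    "simulate_recording",
]

PIGMENT_CLASSES = (
    "blue", "brown", "green", "black", "gray", "amber", "red", "purple", "pink",
)
SKIN_TONES = ("A", "B", "C", "D", "E")


@dataclass(frozen=True)
class SubjectProfile:
    """Ground-truth state of one simulated subject."""

    subject_id: str
    true_age_conc: float  # ug/mL
    bmi: float  # kg/m^2
    diet_score: float  # high-AGE-diet propensity in [0, 1]
    pigment_class: str
    skin_tone: str

    def __post_init__(self) -> None:
        if self.true_age_conc <= 0:
            raise DomainError("true_age_conc must be > 0")
        if not 15.0 <= self.bmi <= 45.0:
            raise DomainError("bmi must lie in [15, 45] kg/m^2")
        if not 0.0 <= self.diet_score <= 1.0:
            raise DomainError("diet_score must lie in [0, 1]")
        if self.pigment_class not in PIGMENT_CLASSES:
            raise DomainError(f"unknown pigment_class {self.pigment_class!r}")
        if self.skin_tone not in SKIN_TONES:
            raise DomainError(f"unknown skin_tone {self.skin_tone!r}")


@dataclass(frozen=True)
class CohortConfig:
    """Cohort-level generating parameters.

    ``true_age_conc = U(age_conc_low, age_conc_high) + diet_effect * diet_score``
    with ``diet_score ~ U(0, 1)``, keeping concentrations inside the
    2-7 ug/mL envelope at the defaults.  BMI is Normal(bmi_mean, bmi_sd)
    plus ``bmi_diet_slope * diet_score``, clipped to [15, 45].
    """

    n_subjects: int = 200
    age_conc_low: float = 2.0  # ug/mL
    age_conc_high: float = 5.5  # ug/mL
    diet_effect: float = 1.5  # ug/mL per unit diet score
    bmi_mean: float = 23.0  # kg/m^2
    bmi_sd: float = 3.0
    bmi_diet_slope: float = 6.0  # kg/m^2 per unit diet score
    assay_cv: float = 0.05  # ELISA coefficient of variation
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ConfigurationError("n_subjects must be >= 1")
        if self.assay_cv < 0:
            raise ConfigurationError("assay_cv must be >= 0")
        if not 0 < self.age_conc_low <= self.age_conc_high:
            raise ConfigurationError("need 0 < age_conc_low <= age_conc_high")
        if self.diet_effect < 0 or self.bmi_sd < 0:
            raise ConfigurationError("diet_effect and bmi_sd must be >= 0")


@dataclass(frozen=True)
class RecordingConfig:
    """Per-recording signal parameters (detector units throughout)."""

    n_samples: int = 500
    n_repeats: int = 3  # repeated measurements per subject, later averaged
    gain: float = 20.0  # detector units per ug/mL
    baseline: float = 50.0
    noise_sd: float = 1.0
    drift_amplitude: float = 6.0  # shared slow illumination drift
    eyelid_baseline: float = 120.0
    eyelid_noise_sd: float = 0.5
    interference_rate: float = 1.5  # expected episodes per recording
    interference_amplitude: Optional[float] = None  # default 3 x noise_sd
    interference_length: int = 150  # samples per episode
    interference_tracking: float = 2.0  # anti-tracking factor vs shared drift
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 2:
            raise ConfigurationError("n_samples must be >= 2")
        if self.n_repeats < 1:
            raise ConfigurationError("n_repeats must be >= 1")
        for name in ("noise_sd", "drift_amplitude", "eyelid_noise_sd",
                     "interference_rate", "interference_tracking"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.interference_amplitude is not None and self.interference_amplitude < 0:
            raise ConfigurationError("interference_amplitude must be >= 0")
        if not 1 <= self.interference_length <= self.n_samples:
            raise ConfigurationError(
                "interference_length must lie in [1, n_samples]"
            )

    @property
    def effective_interference_amplitude(self) -> float:
        if self.interference_amplitude is None:
            return 3.0 * self.noise_sd
        return self.interference_amplitude


@dataclass(frozen=True)
class RawRecording:
    """One two-channel intensity recording plus simulator ground truth."""

    subject_id: str
    repeat_index: int
    corneal: np.ndarray
    eyelid: np.ndarray
    truth_interference_mask: np.ndarray
    truth_episodes: tuple = field(default_factory=tuple)  # (start, length) pairs

    def __post_init__(self) -> None:
        if len(self.corneal) != len(self.eyelid) or len(self.corneal) != len(
            self.truth_interference_mask
        ):
            raise DomainError("corneal, eyelid and truth mask lengths differ")
        if np.any(self.corneal < 0) or np.any(self.eyelid < 0):
            raise DomainError("intensities must be >= 0")

    @property
    def n_samples(self) -> int:
        return len(self.corneal)


def generate_cohort(
    config: CohortConfig,
) -> tuple[list[SubjectProfile], pd.DataFrame]:
    """Draw a cohort of subject profiles and their serum reference table.

    Returns the profiles and a DataFrame with columns ``subject_id,
    true_age_conc, serum_age, bmi, diet_score, pigment_class, skin_tone``.
    Identical config (including seed) yields identical output.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects
    diet = rng.uniform(0.0, 1.0, n)
    base = rng.uniform(config.age_conc_low, config.age_conc_high, n)
    conc = base + config.diet_effect * diet
    bmi = np.clip(
        rng.normal(config.bmi_mean, config.bmi_sd, n)
        + config.bmi_diet_slope * diet,
        15.0,
        45.0,
    )
    pigment = rng.choice(PIGMENT_CLASSES, n)
    skin = rng.choice(SKIN_TONES, n)
    if config.assay_cv > 0:
        # lognormal multiplicative noise with unit mean and the stated CV
        sigma = np.sqrt(np.log1p(config.assay_cv**2))
        serum = conc * rng.lognormal(-0.5 * sigma**2, sigma, n)
    else:
        serum = conc.copy()

    profiles = [
        SubjectProfile(
            subject_id=f"S{i:04d}",
            true_age_conc=float(conc[i]),
            bmi=float(bmi[i]),
            diet_score=float(diet[i]),
            pigment_class=str(pigment[i]),
            skin_tone=str(skin[i]),
        )
        for i in range(n)
    ]
    table = pd.DataFrame(
        {
            "subject_id": [p.subject_id for p in profiles],
            "true_age_conc": conc,
            "serum_age": serum,
            "bmi": bmi,
            "diet_score": diet,
            "pigment_class": pigment,
            "skin_tone": skin,
        }
    )
    return profiles, table


def _recording_rng(
    cfg: RecordingConfig, subject_id: str, repeat_index: int
) -> np.random.Generator:
    # stable per-(subject, repeat) stream derived from the config seed
    tag = zlib.crc32(subject_id.encode("utf8"))
    return np.random.default_rng(
        np.random.SeedSequence([cfg.seed, tag, repeat_index])
    )


def _shared_drift(rng: np.random.Generator, n: int, amplitude: float) -> np.ndarray:
    """Slow illumination drift: three incommensurate sinusoids."""
    t = np.arange(n)
    periods = rng.uniform(150.0, 400.0, 3)
    phases = rng.uniform(0.0, 2.0 * np.pi, 3)
    weights = amplitude * np.array([0.5, 0.3, 0.2])
    drift = np.zeros(n)
    for a, period, phase in zip(weights, periods, phases):
        drift += a * np.sin(2.0 * np.pi * t / period + phase)
    return drift


def simulate_recording(
    profile: SubjectProfile,
    rec_cfg: RecordingConfig,
    attenuation: float = 1.0,
    repeat_index: int = 0,
    rng: Optional[np.random.Generator] = None,
) -> RawRecording:
    """Simulate one two-channel recording for a subject.

    The clean corneal level is ``baseline + gain * true_age_conc *
    attenuation``; both channels share a slow illumination drift; a
    Poisson number of interference episodes push the corneal channel
    against that drift.  ``attenuation`` is the round-trip pigment
    transmittance in (0, 1] (see :mod:`corneafluor.optics`).

    When ``rng`` is omitted, a stream is derived deterministically from
    ``(rec_cfg.seed, subject_id, repeat_index)``, so rebuilding the same
    recording is reproducible without threading generators around.
    """
    if not 0.0 < attenuation <= 1.0:
        raise DomainError("attenuation must lie in (0, 1]")
    if rng is None:
        rng = _recording_rng(rec_cfg, profile.subject_id, repeat_index)

    n = rec_cfg.n_samples
    level = rec_cfg.baseline + rec_cfg.gain * profile.true_age_conc * attenuation
    drift = _shared_drift(rng, n, rec_cfg.drift_amplitude)

    corneal = level + drift
    if rec_cfg.noise_sd > 0:
        corneal = corneal + rng.normal(0.0, rec_cfg.noise_sd, n)
    eyelid = rec_cfg.eyelid_baseline + drift
    if rec_cfg.eyelid_noise_sd > 0:
        eyelid = eyelid + rng.normal(0.0, rec_cfg.eyelid_noise_sd, n)

    mask = np.zeros(n, dtype=bool)
    episodes = []
    amp = rec_cfg.effective_interference_amplitude
    length = min(rec_cfg.interference_length, n)
    n_episodes = rng.poisson(rec_cfg.interference_rate)
    for _ in range(n_episodes):
        start = int(rng.integers(0, n - length + 1))
        seg = drift[start : start + length]
        x = np.arange(length)
        slope = np.polyfit(x, seg, 1)[0] if length > 1 else 0.0
        sign = -np.sign(slope) if slope != 0 else float(rng.choice((-1.0, 1.0)))
        # anti-track the shared drift and add an opposing ramp, so the
        # contaminated corneal trend opposes the eyelid trend
        transient = (
            -(1.0 + rec_cfg.interference_tracking) * (seg - seg[0])
            + sign * amp * x / max(length - 1, 1)
        )
        if np.any(transient != 0.0):
            corneal[start : start + length] += transient
            mask[start : start + length] = True
            episodes.append((start, length))

    return RawRecording(
        subject_id=profile.subject_id,
        repeat_index=repeat_index,
        corneal=np.clip(corneal, 0.0, None),
        eyelid=np.clip(eyelid, 0.0, None),
        truth_interference_mask=mask,
        truth_episodes=tuple(episodes),
    )


def recording_to_frame(recording: RawRecording) -> pd.DataFrame:
    """Tabular view of a recording (CSV interchange schema)."""
    return pd.DataFrame(
        {
            "sample_index": np.arange(recording.n_samples),
            "corneal": recording.corneal,
            "eyelid": recording.eyelid,
            "truth_interference": recording.truth_interference_mask.astype(int),
        }
    )
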