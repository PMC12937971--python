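"""Method-comparison statistics for paired serum vs device AGE values.

Implements the standard agreement toolkit for validating the device
against the serum ELISA reference:

* Pearson product-moment correlation;
* Bland-Altman analysis with differences taken as ``reference - test``
  (serum minus device) and limits of agreement at bias +/- 1.96 SD, the
  sample SD using n-1;
* signed per-pair relative error ``100 * (test - reference) / reference``
  and its mean absolute value (MARE).

The difference direction and the relative-error sign convention are fixed
so a device reading *above* serum yields a negative Bland-Altman
difference and a positive relative error.  1.96 is used verbatim, not a
t-quantile.

A bundled 20-pair clinical comparison dataset (serum ELISA vs device
prediction, ug/mL) ships with the package; its printed relative-error
column was evidently computed from unrounded concentrations, so for some
rows the value recomputed from the two printed concentration columns
differs in the last digit (see ``load_clinical_pairs``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ConstantSeriesError, DomainError, InputError

__all__ = [
    "PairedMeasurements",
    "BlandAltman",
    "AgreementReport",
    "pearson_r",
    "bland_altman",
    "relative_error",
    "mean_abs_relative_error",
    "agreement_report",
    "load_clinical_pairs",
]

REPORT_SCHEMA_VERSION = "1.0"

#: Rows of the bundled comparison table whose printed relative error matches
#: a 1-d.p. recomputation from the two concentration columns; the remaining
#: rows were printed from unrounded intermediate values.
CONSISTENT_ROWS = (1, 2, 6, 7, 12, 14, 17, 20)


@dataclass(frozen=True)
class PairedMeasurements:
    """Reference (serum) and test (device) concentrations, ug/mL."""

    reference: np.ndarray
    test: np.ndarray
    labels: Optional[tuple] = None

    def __post_init__(self) -> None:
        ref = np.asarray(self.reference, dtype=float)
        tst = np.asarray(self.test, dtype=float)
        object.__setattr__(self, "reference", ref)
        object.__setattr__(self, "test", tst)
        if ref.shape != tst.shape or ref.ndim != 1:
            raise InputError("reference and test must be 1-D and equal length")
        if len(ref) < 2:
            raise InputError("need at least 2 pairs")
        if np.any(ref <= 0) or np.any(tst <= 0):
            raise DomainError("concentrations must be > 0")
        if self.labels is not None and len(self.labels) != len(ref):
            raise InputError("labels length must match the pairs")

    def __len__(self) -> int:
        return len(self.reference)


@dataclass(frozen=True)
class BlandAltman:
    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float


def pearson_r(pairs: PairedMeasurements) -> float:
    """Product-moment correlation between reference and test."""
    if len(pairs) < 3:
        raise InputError("pearson_r needs at least 3 pairs")
    if np.std(pairs.reference) == 0 or np.std(pairs.test) == 0:
        raise ConstantSeriesError(
            "correlation is undefined for a constant series"
        )
    return float(stats.pearsonr(pairs.reference, pairs.test).statistic)


def bland_altman(pairs: PairedMeasurements) -> BlandAltman:
    """Bias and 95% limits of agreement of ``reference - test``."""
    diff = pairs.reference - pairs.test
    bias = float(np.mean(diff))
    sd = float(np.std(diff, ddof=1))
    return BlandAltman(bias, sd, bias - 1.96 * sd, bias + 1.96 * sd)


def relative_error(reference, test):
    """Signed percent error of the device vs the reference.

    ``100 * (test - reference) / reference``; positive when the device
    reads high.  Accepts scalars or arrays; the reference must be > 0.
    """
    reference = np.asarray(reference, dtype=float)
    test = np.asarray(test, dtype=float)
    if np.any(reference <= 0):
        raise DomainError("reference concentration must be > 0")
    out = 100.0 * (test - reference) / reference
    return float(out) if out.ndim == 0 else out


def mean_abs_relative_error(pairs: PairedMeasurements) -> float:
    """Mean of |relative error| over the pairs, in percent."""
    return float(np.mean(np.abs(relative_error(pairs.reference, pairs.test))))


@dataclass(frozen=True)
class AgreementReport:
    """Full agreement summary between the device and the serum reference."""

    n: int
    pearson_r: float
    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float
    per_pair_relative_error: tuple
    mean_abs_relative_error: float
    schema_version: str = REPORT_SCHEMA_VERSION

    def to_json(self, indent: int = 2) -> str:
        payload = {
            "schema_version": self.schema_version,
            "n": self.n,
            "conventions": {
                "difference": "reference - test",
                "relative_error": "100 * (test - reference) / reference",
                "loa_multiplier": 1.96,
            },
            "pearson_r": self.pearson_r,
            "bland_altman": {
                "bias": self.bias,
                "sd_diff": self.sd_diff,
                "loa_low": self.loa_low,
                "loa_high": self.loa_high,
            },
            "per_pair_relative_error_percent": list(self.per_pair_relative_error),
            "mean_abs_relative_error_percent": self.mean_abs_relative_error,
        }
        return json.dumps(payload, indent=indent, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "AgreementReport":
        payload = json.loads(text)
        version = payload.get("schema_version", "0")
        if version.split(".")[0] != REPORT_SCHEMA_VERSION.split(".")[0]:
            from .exceptions import SchemaVersionError

            raise SchemaVersionError(
                f"unsupported report schema version {version!r}"
            )
        ba = payload["bland_altman"]
        return cls(
            n=payload["n"],
            pearson_r=payload["pearson_r"],
            bias=ba["bias"],
            sd_diff=ba["sd_diff"],
            loa_low=ba["loa_low"],
            loa_high=ba["loa_high"],
            per_pair_relative_error=tuple(
                payload["per_pair_relative_error_percent"]
            ),
            mean_abs_relative_error=payload["mean_abs_relative_error_percent"],
            schema_version=version,
        )

    def render_text(self) -> str:
        lines = [
            f"Method agreement over n = {self.n} pairs",
            "(differences are reference - test; relative error is",
            " 100 * (test - reference) / reference; limits at 1.96 SD)",
            f"  Pearson r:              {self.pearson_r:.3f}",
            f"  Bland-Altman bias:      {self.bias:.3f}",
            f"  SD of differences:      {self.sd_diff:.3f}",
            f"  Limits of agreement:    {self.loa_low:.3f} to {self.loa_high:.3f}",
            f"  Mean |relative error|:  {self.mean_abs_relative_error:.1f}%",
        ]
        return "\n".join(lines)


def agreement_report(pairs: PairedMeasurements) -> AgreementReport:
    """Compute all agreement statistics for one paired dataset."""
    r = pearson_r(pairs)
    ba = bland_altman(pairs)
    per_pair = relative_error(pairs.reference, pairs.test)
    return AgreementReport(
        n=len(pairs),
        pearson_r=r,
        bias=ba.bias,
        sd_diff=ba.sd_diff,
        loa_low=ba.loa_low,
        loa_high=ba.loa_high,
        per_pair_relative_error=tuple(float(v) for v in per_pair),
        mean_abs_relative_error=float(np.mean(np.abs(per_pair))),
    )


def load_clinical_pairs() -> tuple[PairedMeasurements, pd.DataFrame]:
    """Bundled 20-pair serum vs device comparison dataset.

    Returns the pairs plus the full table, whose columns are ``serial``,
    ``serum_age``, ``predicted_age`` and ``printed_relative_error`` (the
    error value as originally reported; see :data:`CONSISTENT_ROWS` for
    the rows where it matches a 1-d.p. recomputation).
    """
    with resources.files("corneafluor.data").joinpath("clinical_pairs.csv").open() as fh:
        table = pd.read_csv(fh)
    pairs = PairedMeasurements(
        reference=table["serum_age"].to_numpy(),
        test=table["predicted_age"].to_numpy(),
        labels=tuple(int(s) for s in table["serial"]),
    )
    return pairs, table
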