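"""Band-level Beer-Lambert model of pigment and skin-tone attenuation.

Iris pigment (melanin, xanthophyll mixtures) absorbs both the 365 nm
excitation light on its way into the tissue and the emitted fluorescence on
its way out.  Rather than rendering full spectra, the model collapses each
pigment to two effective decadic absorbance coefficients -- one at the
excitation band, one at the emission band -- and computes a single
round-trip transmittance factor.  Scattering is folded into the effective
coefficients.

Skin tone enters as a multiplicative absorbance scale on the ordinal
light-to-dark scale A..E (A = 1.0, linear to E = 1.4), reflecting the
wrist-validation pathway where darker tones attenuate more.

The bundled per-pigment coefficient table (``data/pigments.csv``) is a
synthetic calibration fixture: values are chosen so the attenuation ranking
reproduces the qualitative interference ordering observed on the device
(purple and blue strongest; green and pink weakest), not measured spectra.
Users with measured coefficients can substitute their own table.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .exceptions import DomainError, InputError

__all__ = [
    "PigmentSpec",
    "OpticalPath",
    "SKIN_TONE_FACTORS",
    "load_pigment_table",
    "transmittance",
    "rank_interference",
]

#: Multiplicative absorbance scaling per ordinal skin tone, light to dark.
SKIN_TONE_FACTORS = {"A": 1.0, "B": 1.1, "C": 1.2, "D": 1.3, "E": 1.4}


@dataclass(frozen=True)
class PigmentSpec:
    """Effective decadic absorbance of one pigment class.

    Coefficients are per unit concentration (g/100 mL) and unit path (cm),
    at the excitation (365 nm) and emission bands respectively.
    """

    name: str
    abs_excitation: float
    abs_emission: float

    def __post_init__(self) -> None:
        if self.abs_excitation < 0 or self.abs_emission < 0:
            raise DomainError(
                f"pigment {self.name!r}: absorbances must be >= 0"
            )


@dataclass(frozen=True)
class OpticalPath:
    """Geometry and loading of the absorbing path.

    ``skin_tone_factor`` scales total absorbance (1.0 for the lightest
    tone); use :data:`SKIN_TONE_FACTORS` to map the ordinal classes.
    """

    path_length: float = 1.0  # cm
    pigment_conc: float = 0.0  # g/100 mL
    skin_tone_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.path_length <= 0:
            raise DomainError("path_length must be > 0")
        if self.pigment_conc < 0:
            raise DomainError("pigment_conc must be >= 0")
        if self.skin_tone_factor < 1.0:
            raise DomainError("skin_tone_factor must be >= 1 (A maps to 1.0)")


def load_pigment_table() -> pd.DataFrame:
    """Return the bundled pigment coefficient table (synthetic fixture)."""
    with resources.files("corneafluor.data").joinpath("pigments.csv").open() as fh:
        return pd.read_csv(fh)


def load_pigment_specs() -> dict[str, PigmentSpec]:
    """Bundled table as a name -> :class:`PigmentSpec` mapping."""
    table = load_pigment_table()
    return {
        row["name"]: PigmentSpec(row["name"], row.abs_excitation, row.abs_emission)
        for _, row in table.iterrows()
    }


def transmittance(spec: PigmentSpec, path: OpticalPath) -> float:
    """Round-trip transmittance factor in (0, 1].

    Decadic Beer-Lambert with the excitation and emission absorbances
    summed over the same path::

        T = 10 ** (-(a_ex + a_em) * c * l * s)

    where ``c`` is pigment concentration, ``l`` the path length and ``s``
    the skin-tone scale.  Equals 1 exactly when ``c == 0``.
    """
    exponent = (
        (spec.abs_excitation + spec.abs_emission)
        * path.pigment_conc
        * path.path_length
        * path.skin_tone_factor
    )
    return float(10.0 ** (-exponent))


def rank_interference(
    specs: list[PigmentSpec], path: OpticalPath
) -> list[PigmentSpec]:
    """Order pigments by attenuation strength, strongest first.

    Sorting is stable and descending in ``1 - transmittance``; exact ties
    are broken lexicographically by pigment name, preserving input order
    for identical (attenuation, name) pairs.
    """
    if len(specs) < 2:
        raise InputError("rank_interference needs at least two pigment specs")
    attenuations = [1.0 - transmittance(s, path) for s in specs]
    order = sorted(
        range(len(specs)),
        key=lambda i: (-attenuations[i], specs[i].name),
    )
    return [specs[i] for i in order]


def subject_transmittance(
    pigment_class: str,
    skin_tone: str,
    pigment_conc: float,
    path_length: float = 1.0,
) -> float:
    """Transmittance for a subject given pigment class and skin tone letter."""
    specs = load_pigment_specs()
    if pigment_class not in specs:
        raise DomainError(f"unknown pigment class {pigment_class!r}")
    if skin_tone not in SKIN_TONE_FACTORS:
        raise DomainError(f"unknown skin tone {skin_tone!r} (expected A..E)")
    path = OpticalPath(
        path_length=path_length,
        pigment_conc=pigment_conc,
        skin_tone_factor=SKIN_TONE_FACTORS[skin_tone],
    )
    return transmittance(specs[pigment_class], path)
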