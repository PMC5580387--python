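"""The 12-character diagnostic scheme for last-cervical vs first-thoracic vertebrae.

Twelve discrete characters, lettered ``a``--``l``, each of which can take a
cervical-type, transitional, or thoracic-type state on a given vertebra.
Five characters (``b`` in juveniles, ``d``, ``e``, ``f``, ``j``) have numeric
ratio criteria and can be scored directly from raw measurements; the rest are
qualitative and their states are data-entry inputs.

A *character profile* maps character letters to states.  Bilateral characters
may instead map to a :class:`SideStates` pair; the specimen-level state used
for counting is the more thoracic of the two sides (a facet on one side still
evidences homeotic change).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from typing import Mapping, Optional, Union

from .errors import InvalidMeasurementError, UnsupportedCharacterError

logger = logging.getLogger(__name__)

CHARACTER_IDS = tuple("abcdefghijkl")

#: Characters scored separately on the left and right side.
BILATERAL_IDS = frozenset("fhijkl")

#: Characters with numeric ratio criteria (b only in juveniles).
QUANTITATIVE_IDS = frozenset("bdefj")

#: The two rib-facet characters (transverse process / centrum).
RIB_FACET_IDS = ("k", "l")


class CharacterState(Enum):
    """Trichotomous character state; MISSING never contributes to counts."""

    CERVICAL = "C"
    TRANSITIONAL = "X"
    THORACIC = "T"
    MISSING = "?"

    def __repr__(self) -> str:  # terser than the Enum default in test output
        return f"<{self.name}>"


# Ordering used to pick the specimen-level state of a bilateral character:
# the more thoracic side wins; a known state always beats MISSING.
_THORACIC_RANK = {
    CharacterState.MISSING: 0,
    CharacterState.CERVICAL: 1,
    CharacterState.TRANSITIONAL: 2,
    CharacterState.THORACIC: 3,
}


@dataclass(frozen=True)
class SideStates:
    """Per-side states of a bilateral character."""

    left: CharacterState
    right: CharacterState

    @property
    def effective(self) -> CharacterState:
        return max(self.left, self.right, key=_THORACIC_RANK.__getitem__)

    @property
    def discordant(self) -> bool:
        """True when both sides are informative and disagree."""
        if CharacterState.MISSING in (self.left, self.right):
            return False
        return self.left != self.right


ProfileEntry = Union[CharacterState, SideStates]
CharacterProfile = Mapping[str, ProfileEntry]


class AnatomicalElement(Enum):
    CENTRUM = "centrum"
    VERTEBRAL_FORAMEN = "vertebral_foramen"
    PREZYGAPOPHYSIS = "prezygapophysis"
    POSTZYGAPOPHYSIS = "postzygapophysis"
    MPT_ARCH = "MPT_arch"
    RIB_FACET = "rib_facet"


class View(Enum):
    ROSTRAL = "rostral"
    CAUDAL = "caudal"
    VENTRAL = "ventral"
    LATERAL = "lateral"
    DORSAL = "dorsal"


@dataclass(frozen=True)
class CharacterDefinition:
    """One diagnostic character: its anatomy and its end-member criteria."""

    id: str
    anatomical_element: AnatomicalElement
    view: View
    c7_criterion: str
    t1_criterion: str
    quantitative: bool
    bilateral: bool
    age_variant: bool = False


_E, _V = AnatomicalElement, View

DEFINITIONS: dict[str, CharacterDefinition] = {
    d.id: d
    for d in (
        CharacterDefinition(
            "a", _E.CENTRUM, _V.ROSTRAL,
            "anterior articular face oval, higher than wide, dorsal border convex",
            "anterior articular face heart-shaped, at least as wide as high, dorsal border straight",
            quantitative=False, bilateral=False,
        ),
        CharacterDefinition(
            "b", _E.CENTRUM, _V.CAUDAL,
            "posterior end: dorsal width clearly exceeds ventral width, ventrally convex"
            " (juvenile: height/width >= 69%)",
            "posterior end squarish, dorsal width ~ ventral width, ventrally straight/tapering"
            " (juvenile: height/width < 64%)",
            quantitative=True, bilateral=False, age_variant=True,
        ),
        CharacterDefinition(
            "c", _E.CENTRUM, _V.VENTRAL,
            "ventral keel with strongly developed median tubercle(s)",
            "ventral keel without tubercles, at most very weakly developed",
            quantitative=False, bilateral=False,
        ),
        CharacterDefinition(
            "d", _E.CENTRUM, _V.VENTRAL,
            "anterior articular face deep and rounded, A-P length 40-50% of centrum width",
            "anterior articular face shallow and flat, A-P length 25-35% of centrum width",
            quantitative=True, bilateral=False,
        ),
        CharacterDefinition(
            "e", _E.VERTEBRAL_FORAMEN, _V.ROSTRAL,
            "foramen wide: height/width ratio 75% or more",
            "foramen narrow: height/width ratio 73% or smaller",
            quantitative=True, bilateral=False,
        ),
        CharacterDefinition(
            "f", _E.PREZYGAPOPHYSIS, _V.ROSTRAL,
            "left-right gap large: shortest distance ~50% of total width at that level",
            "left-right gap small: shortest distance ~35% of total width at that level",
            quantitative=True, bilateral=True,
        ),
        CharacterDefinition(
            "g", _E.PREZYGAPOPHYSIS, _V.DORSAL,
            "prezygapophysis more anterior than transverse process",
            "prezygapophysis overhangs transverse process",
            quantitative=False, bilateral=False,
        ),
        CharacterDefinition(
            "h", _E.POSTZYGAPOPHYSIS, _V.LATERAL,
            "articular facet visible for greatest part (latero-caudally directed)",
            "articular facet at most minimally visible (caudally directed)",
            quantitative=False, bilateral=True,
        ),
        CharacterDefinition(
            "i", _E.POSTZYGAPOPHYSIS, _V.CAUDAL,
            "articular facets widely spaced, inner side lateral of neural spine",
            "articular facets narrowly spaced, inner side close to centre of neural spine",
            quantitative=False, bilateral=True,
        ),
        CharacterDefinition(
            "j", _E.MPT_ARCH, _V.ROSTRAL,
            "outer arch long: at least 85% of centrum height",
            "outer arch short: at most 70% of centrum height",
            quantitative=True, bilateral=True,
        ),
        CharacterDefinition(
            "k", _E.RIB_FACET, _V.LATERAL,
            "rib facet at transverse process absent",
            "rib facet at transverse process present (large)",
            quantitative=False, bilateral=True,
        ),
        CharacterDefinition(
            "l", _E.RIB_FACET, _V.ROSTRAL,
            "rib facet at centrum absent",
            "rib facet at centrum present (large)",
            quantitative=False, bilateral=True,
        ),
    )
}

SCHEME_VERSION = "1.0"


class AgeClass(Enum):
    ADULT = "adult"
    JUVENILE = "juvenile"
    UNKNOWN = "unknown"


@dataclass(frozen=True)
class MeasurementSet:
    """Raw quantities (consistent length units) from which ratio characters derive.

    Only the fields needed for the requested character must be present.
    """

    foramen_height: Optional[float] = None      # e
    foramen_width: Optional[float] = None
    articular_ap_length: Optional[float] = None  # d
    centrum_width: Optional[float] = None
    prezyg_gap: Optional[float] = None           # f
    total_width_at_level: Optional[float] = None
    arch_length: Optional[float] = None          # j
    centrum_height: Optional[float] = None
    posterior_width: Optional[float] = None      # b (juvenile)
    posterior_height: Optional[float] = None
    age_class: AgeClass = AgeClass.UNKNOWN


@dataclass(frozen=True)
class _RatioBand:
    """One-dimensional decision rule: cervical band sits above the thoracic band.

    ``ratio >= c7_lower`` (or ``>`` if exclusive) scores CERVICAL,
    ``ratio <= t1_upper`` (or ``<``) scores THORACIC, and the open gap in
    between scores TRANSITIONAL.  Values beyond a band on its own side take
    that band's state, so the rule is a monotone step function of the ratio.
    """

    numerator: str
    denominator: str
    c7_lower: float
    t1_upper: float
    c7_inclusive: bool = True
    t1_inclusive: bool = True

    def score(self, ratio: float) -> CharacterState:
        in_c7 = ratio >= self.c7_lower if self.c7_inclusive else ratio > self.c7_lower
        if in_c7:
            return CharacterState.CERVICAL
        in_t1 = ratio <= self.t1_upper if self.t1_inclusive else ratio < self.t1_upper
        if in_t1:
            return CharacterState.THORACIC
        return CharacterState.TRANSITIONAL


# Thresholds come from the printed ratio criteria of the scoring scheme.
# Gaps between the bands are scored TRANSITIONAL (declared convention).
RATIO_BANDS: dict[str, _RatioBand] = {
    "b": _RatioBand("posterior_height", "posterior_width", 0.69, 0.64,
                    t1_inclusive=False),          # juvenile only; T1 strictly < 64%
    "d": _RatioBand("articular_ap_length", "centrum_width", 0.40, 0.35),
    "e": _RatioBand("foramen_height", "foramen_width", 0.75, 0.73),
    "f": _RatioBand("prezyg_gap", "total_width_at_level", 0.50, 0.35),
    "j": _RatioBand("arch_length", "centrum_height", 0.85, 0.70),
}


def state_from_measurement(char_id: str, m: MeasurementSet) -> CharacterState:
    """Score a quantitative character from raw measurements.

    Returns MISSING when the required measurements are absent.  Character
    ``b`` only has a numeric criterion in juveniles; for adult (or unknown,
    which falls back to the adult criterion with a warning) age classes it
    must be scored qualitatively and an :class:`UnsupportedCharacterError`
    is raised.
    """
    if char_id not in DEFINITIONS:
        raise UnsupportedCharacterError(f"unknown character id: {char_id!r}")
    if char_id not in RATIO_BANDS:
        raise UnsupportedCharacterError(
            f"character {char_id!r} is qualitative; its state is a data-entry input"
        )
    if char_id == "b":
        if m.age_class is AgeClass.UNKNOWN:
            logger.warning(
                "age class unknown; character 'b' falls back to the adult "
                "(qualitative) criterion"
            )
        if m.age_class is not AgeClass.JUVENILE:
            raise UnsupportedCharacterError(
                "character 'b' has a numeric criterion only for juveniles; "
                "adult states are qualitative data-entry inputs"
            )

    band = RATIO_BANDS[char_id]
    num = getattr(m, band.numerator)
    den = getattr(m, band.denominator)
    if num is None or den is None:
        return CharacterState.MISSING
    if den <= 0 or num <= 0:
        raise InvalidMeasurementError(
            f"character {char_id!r}: measurements must be strictly positive "
            f"({band.numerator}={num}, {band.denominator}={den})"
        )
    return band.score(num / den)


def effective_state(entry: ProfileEntry) -> CharacterState:
    """Specimen-level state of a profile entry (more thoracic side wins)."""
    if isinstance(entry, SideStates):
        return entry.effective
    return entry


def state_counts(profile: CharacterProfile) -> dict[CharacterState, int]:
    """Counts of effective states over all 12 characters; absent ids are MISSING."""
    counts = {s: 0 for s in CharacterState}
    for cid in CHARACTER_IDS:
        entry = profile.get(cid)
        state = CharacterState.MISSING if entry is None else effective_state(entry)
        counts[state] += 1
    return counts


def validate_profile(profile: CharacterProfile) -> list[str]:
    """Return human-readable findings about a profile; never raises, never mutates."""
    findings: list[str] = []
    for key, entry in profile.items():
        if key not in DEFINITIONS:
            findings.append(f"unknown character id: {key!r}")
            continue
        if isinstance(entry, SideStates) and not DEFINITIONS[key].bilateral:
            findings.append(
                f"per-side states given for non-bilateral character {key!r}"
            )
        elif not isinstance(entry, (SideStates, CharacterState)):
            findings.append(f"character {key!r}: not a CharacterState or SideStates")

    informative = sum(
        1
        for key, entry in profile.items()
        if key in DEFINITIONS
        and isinstance(entry, (SideStates, CharacterState))
        and effective_state(entry) is not CharacterState.MISSING
    )
    if informative == 0:
        findings.append("no informative characters")
    return findings


def definitions_table():
    """The character dictionary as a tidy table (one row per character)."""
    import pandas as pd

    rows = [
        {
            "id": d.id,
            "anatomical_element": d.anatomical_element.value,
            "view": d.view.value,
            "c7_criterion": d.c7_criterion,
            "t1_criterion": d.t1_criterion,
            "quantitative": d.quantitative,
            "bilateral": d.bilateral,
            "age_variant": d.age_variant,
        }
        for d in DEFINITIONS.values()
    ]
    df = pd.DataFrame(rows).set_index("id")
    df.attrs["scheme_version"] = SCHEME_VERSION
    return df


def export_definitions(path, fmt: str = "csv") -> None:
    """Write the character dictionary as delimited text or a YAML config block."""
    df = definitions_table()
    if fmt == "csv":
        df.to_csv(path)
    elif fmt == "yaml":
        import yaml

        payload = {
            "scheme_version": SCHEME_VERSION,
            "characters": df.reset_index().to_dict(orient="records"),
            "ratio_bands": {
                cid: {
                    "numerator": b.numerator,
                    "denominator": b.denominator,
                    "c7_lower": b.c7_lower,
                    "t1_upper": b.t1_upper,
                    "c7_inclusive": b.c7_inclusive,
                    "t1_inclusive": b.t1_inclusive,
                }
                for cid, b in RATIO_BANDS.items()
            },
        }
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)
    else:
        raise ValueError(f"unknown format: {fmt!r}")
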