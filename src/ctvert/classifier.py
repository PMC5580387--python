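"""Vertebral identity calls from character profiles.

The decision rule: a vertebra with no rib facets is a last cervical (C7).
A facet-bearing vertebra with six or more of its 12 characters in a cervical
or transitional state — i.e. at least 50% cervical in morphology — is a
transitional cervico-thoracic (C/T) vertebra; a facet-bearing vertebra below
that threshold is a regular first thoracic (T1).  When the facet status or
the threshold cannot be resolved because of missing characters, the call is
INDETERMINATE and excluded from downstream denominators.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Optional

import pandas as pd

from .characters import (
    BILATERAL_IDS,
    CHARACTER_IDS,
    RIB_FACET_IDS,
    AgeClass,
    CharacterProfile,
    CharacterState,
    MeasurementSet,
    SideStates,
    effective_state,
    state_counts,
    validate_profile,
)
from .errors import DuplicateSpecimenError, ProfileError

logger = logging.getLogger(__name__)

#: Minimum number of cervical-or-transitional characters (out of 12) for a
#: facet-bearing vertebra to be called transitional C/T rather than T1.
CT_THRESHOLD = 6


class Identity(Enum):
    C7 = "C7"
    CT = "C/T"
    T1 = "T1"
    INDETERMINATE = "indeterminate"


class FacetSize(Enum):
    NONE = "none"
    SMALL = "small"
    LARGE = "large"


@dataclass(frozen=True)
class SideNotes:
    """Free-form per-side rib facet annotations."""

    facet_left: Optional[FacetSize] = None
    facet_right: Optional[FacetSize] = None
    position_note: str = ""

    @property
    def size_asymmetric(self) -> bool:
        if self.facet_left is None or self.facet_right is None:
            return False
        return self.facet_left != self.facet_right

    @property
    def position_asymmetric(self) -> bool:
        # A position note is only recorded when the two sides differ.
        return bool(self.position_note.strip())


@dataclass
class VertebraRecord:
    """One vertebra: provenance plus its character profile."""

    specimen_id: str
    taxon: str = ""
    age_class: AgeClass = AgeClass.UNKNOWN
    locality: str = ""
    profile: CharacterProfile = field(default_factory=dict)
    measurements: Optional[MeasurementSet] = None
    side_notes: Optional[SideNotes] = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.specimen_id:
            raise ValueError("specimen_id must be non-empty")


@dataclass(frozen=True)
class IdentityCall:
    identity: Identity
    n_cervical: int
    n_transitional: int
    n_thoracic: int
    n_missing: int
    rib_facets_present: Optional[bool]
    asymmetric: bool

    def __post_init__(self) -> None:
        total = self.n_cervical + self.n_transitional + self.n_thoracic + self.n_missing
        if total != len(CHARACTER_IDS):
            raise ValueError(f"state counts must sum to 12, got {total}")
        if self.identity is Identity.CT and not self.rib_facets_present:
            raise ValueError("C/T calls must have rib facets")
        if self.identity is Identity.C7 and self.rib_facets_present:
            raise ValueError("C7 calls must lack rib facets")


def rib_facets_present(profile: CharacterProfile) -> Optional[bool]:
    """Whether either rib-facet character (k: transverse process, l: centrum)
    shows a facet on any side.

    Returns True if k or l is TRANSITIONAL or THORACIC, False if both are
    CERVICAL, and None (indeterminate — never guessed) when both are MISSING.
    """
    states = []
    for cid in RIB_FACET_IDS:
        entry = profile.get(cid)
        states.append(
            CharacterState.MISSING if entry is None else effective_state(entry)
        )
    if any(s in (CharacterState.TRANSITIONAL, CharacterState.THORACIC) for s in states):
        return True
    if all(s is CharacterState.MISSING for s in states):
        return None
    # At least one facet character observed cervical, none non-cervical.
    if any(s is CharacterState.MISSING for s in states):
        # One facet site unobservable: a facet could still hide there.
        return None
    return False


def asymmetry_flag(record: VertebraRecord) -> bool:
    """True when any bilateral character or facet annotation differs between sides."""
    has_side_info = False
    for cid in BILATERAL_IDS:
        entry = record.profile.get(cid)
        if isinstance(entry, SideStates):
            has_side_info = True
            if entry.discordant:
                return True
    notes = record.side_notes
    if notes is not None:
        has_side_info = True
        if notes.size_asymmetric or notes.position_asymmetric:
            return True
    if not has_side_info:
        logger.debug(
            "specimen %s: no per-side information; asymmetry flag defaults to False",
            record.specimen_id,
        )
    return False


def classify(record: VertebraRecord) -> IdentityCall:
    """Assign a vertebral identity from the record's character profile."""
    findings = [
        f
        for f in validate_profile(record.profile)
        if f != "no informative characters"  # handled below as INDETERMINATE
    ]
    if findings:
        raise ProfileError(
            f"specimen {record.specimen_id!r}: " + "; ".join(findings)
        )

    counts = state_counts(record.profile)
    n_c = counts[CharacterState.CERVICAL]
    n_x = counts[CharacterState.TRANSITIONAL]
    n_t = counts[CharacterState.THORACIC]
    n_m = counts[CharacterState.MISSING]

    facets = rib_facets_present(record.profile)
    if facets is None:
        identity = Identity.INDETERMINATE
    elif not facets:
        identity = Identity.C7
    elif n_c + n_x >= CT_THRESHOLD:
        identity = Identity.CT
    elif n_c + n_x + n_m < CT_THRESHOLD:
        # Even crediting every missing character as cervical cannot reach
        # the threshold, so the call is safely T1.
        identity = Identity.T1
    else:
        identity = Identity.INDETERMINATE

    return IdentityCall(
        identity=identity,
        n_cervical=n_c,
        n_transitional=n_x,
        n_thoracic=n_t,
        n_missing=n_m,
        rib_facets_present=facets,
        asymmetric=asymmetry_flag(record),
    )


def classify_dataset(records: Iterable[VertebraRecord]) -> pd.DataFrame:
    """Classify every record; returns a frame indexed by specimen id.

    Columns: identity, n_cervical, n_transitional, n_thoracic, n_missing,
    rib_facets_present, asymmetric.  Row order follows the input.  Summary
    counts by identity are attached as ``df.attrs["summary"]``.
    """
    rows = []
    seen: set[str] = set()
    for rec in records:
        if rec.specimen_id in seen:
            raise DuplicateSpecimenError(rec.specimen_id)
        seen.add(rec.specimen_id)
        call = classify(rec)
        rows.append(
            {
                "specimen_id": rec.specimen_id,
                "identity": call.identity.value,
                "n_cervical": call.n_cervical,
                "n_transitional": call.n_transitional,
                "n_thoracic": call.n_thoracic,
                "n_missing": call.n_missing,
                "rib_facets_present": call.rib_facets_present,
                "asymmetric": call.asymmetric,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "specimen_id",
            "identity",
            "n_cervical",
            "n_transitional",
            "n_thoracic",
            "n_missing",
            "rib_facets_present",
            "asymmetric",
        ],
    ).set_index("specimen_id")
    df.attrs["summary"] = identity_summary(df)
    return df


def identity_summary(calls: pd.DataFrame) -> dict[str, int]:
    """Counts by identity, with zero entries for absent identities."""
    counts = calls["identity"].value_counts().to_dict() if len(calls) else {}
    return {ident.value: int(counts.get(ident.value, 0)) for ident in Identity}
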