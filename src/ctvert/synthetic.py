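"""Synthetic specimen populations with known ground truth.

Used to property-test the classifier, calibrate the exact test (type-I
error) and estimate power, with no external data.  All randomness flows
through numpy Generators seeded from explicit integers; two calls with the
same model and seed produce identical output.

Archetype construction: C7 archetypes are all-cervical; C/T archetypes carry
non-cervical rib-facet characters and a cervical+transitional total drawn
uniformly from 6-10 (the range seen in real transitional specimens); T1
archetypes carry large facets and at most 5 cervical+transitional
characters.  Noise moves single states one step along
CERVICAL <-> TRANSITIONAL <-> THORACIC, never two steps at once.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from functools import lru_cache
from typing import Optional

import numpy as np

from .characters import (
    BILATERAL_IDS,
    CHARACTER_IDS,
    AgeClass,
    CharacterState,
    SideStates,
)
from .classifier import Identity, VertebraRecord, classify
from .stats import ContingencyTable2x2, IncidenceResult, fisher_exact, incidence

_STATES = (CharacterState.CERVICAL, CharacterState.TRANSITIONAL, CharacterState.THORACIC)
_STATE_INDEX = {s: i for i, s in enumerate(_STATES)}

CT_MIX_RANGE = (6, 10)  # cervical+transitional total drawn for C/T archetypes


@dataclass(frozen=True)
class PopulationModel:
    """Generating process for one specimen population."""

    n_specimens: int
    prevalence_ct: float = 0.0
    prevalence_t1_contaminant: float = 0.0
    state_noise: float = 0.0
    missing_rate: float = 0.0
    asymmetry_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_specimens < 0:
            raise ValueError("n_specimens must be >= 0")
        for name in (
            "prevalence_ct",
            "prevalence_t1_contaminant",
            "state_noise",
            "missing_rate",
            "asymmetry_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.prevalence_ct + self.prevalence_t1_contaminant > 1.0:
            raise ValueError("prevalence_ct + prevalence_t1_contaminant must be <= 1")


@dataclass(frozen=True)
class MonteCarloEstimate:
    """A simulated rejection fraction with an exact binomial CI."""

    rate: float
    ci_low: float
    ci_high: float
    reps: int
    n_rejections: int
    seed: int

    @property
    def mc_standard_error(self) -> float:
        p = self.rate
        return (p * (1 - p) / self.reps) ** 0.5


def _archetype(kind: Identity, rng: np.random.Generator) -> dict[str, CharacterState]:
    """A clean, complete 12-character profile of the given true identity."""
    if kind is Identity.C7:
        return {cid: CharacterState.CERVICAL for cid in CHARACTER_IDS}

    profile = {cid: CharacterState.THORACIC for cid in CHARACTER_IDS}
    others = [cid for cid in CHARACTER_IDS if cid not in ("k", "l")]
    if kind is Identity.CT:
        # Facets present but reduced; cervical+transitional total in 6..10.
        profile["k"] = CharacterState.TRANSITIONAL
        profile["l"] = CharacterState.TRANSITIONAL
        target = int(rng.integers(CT_MIX_RANGE[0], CT_MIX_RANGE[1] + 1))
        n_cervical = target - 2  # k and l already count as transitional
        for cid in rng.choice(others, size=n_cervical, replace=False):
            profile[cid] = CharacterState.CERVICAL
    elif kind is Identity.T1:
        # Large facets; at most 5 characters stray toward cervical.
        n_stray = int(rng.integers(0, 6))
        for cid in rng.choice(others, size=n_stray, replace=False):
            profile[cid] = rng.choice(
                [CharacterState.CERVICAL, CharacterState.TRANSITIONAL]
            )
    else:  # pragma: no cover - archetypes are only C7/CT/T1
        raise ValueError(f"no archetype for {kind}")
    return profile


def _perturb_one_step(
    state: CharacterState, rng: np.random.Generator
) -> CharacterState:
    """Move one step along the C <-> X <-> T axis; never a two-step jump.

    Pole states step inward (toward the opposite identity); a transitional
    state steps to a uniformly chosen pole.
    """
    i = _STATE_INDEX[state]
    if state is CharacterState.TRANSITIONAL:
        return _STATES[i + int(rng.choice([-1, 1]))]
    return CharacterState.TRANSITIONAL


def generate_population(model: PopulationModel) -> list[VertebraRecord]:
    """Draw a specimen population; pure function of (model, seed).

    Each record carries its true archetype label in
    ``metadata["true_identity"]`` and the model seed in
    ``metadata["seed"]``.
    """
    rng = np.random.default_rng(model.seed)
    records: list[VertebraRecord] = []
    u = rng.random(model.n_specimens)
    for i in range(model.n_specimens):
        if u[i] < model.prevalence_ct:
            kind = Identity.CT
        elif u[i] < model.prevalence_ct + model.prevalence_t1_contaminant:
            kind = Identity.T1
        else:
            kind = Identity.C7
        profile: dict = _archetype(kind, rng)

        if model.state_noise > 0:
            for cid in CHARACTER_IDS:
                if rng.random() < model.state_noise:
                    profile[cid] = _perturb_one_step(profile[cid], rng)
        if model.missing_rate > 0:
            for cid in CHARACTER_IDS:
                if rng.random() < model.missing_rate:
                    profile[cid] = CharacterState.MISSING
        if (
            kind is Identity.CT
            and model.asymmetry_rate > 0
            and rng.random() < model.asymmetry_rate
        ):
            # Make one bilateral character discordant without changing the
            # effective (more thoracic) state used for counting.
            candidates = [
                cid
                for cid in sorted(BILATERAL_IDS)
                if profile[cid]
                in (CharacterState.TRANSITIONAL, CharacterState.THORACIC)
            ]
            if candidates:
                cid = str(rng.choice(candidates))
                s = profile[cid]
                milder = _STATES[_STATE_INDEX[s] - 1]
                left, right = (
                    (milder, s) if rng.random() < 0.5 else (s, milder)
                )
                profile[cid] = SideStates(left=left, right=right)

        records.append(
            VertebraRecord(
                specimen_id=f"SYN-{model.seed}-{i:05d}",
                taxon="synthetic",
                age_class=AgeClass.ADULT,
                locality="in silico",
                profile=profile,
                metadata={"true_identity": kind.value, "seed": model.seed},
            )
        )
    return records


@lru_cache(maxsize=100_000)
def _cached_p_two(a: int, b: int, c: int, d: int) -> float:
    return fisher_exact(ContingencyTable2x2(a, b, c, d)).p_two_sided


def _group_ct_c7(records: list[VertebraRecord]) -> tuple[int, int]:
    n_ct = n_c7 = 0
    for rec in records:
        ident = classify(rec).identity
        if ident is Identity.CT:
            n_ct += 1
        elif ident is Identity.C7:
            n_c7 += 1
    return n_ct, n_c7


def _rejection_rate(
    prevalence_a: float,
    prevalence_b: float,
    n_a: int,
    n_b: int,
    alpha: float,
    reps: int,
    seed: int,
    base_model: Optional[PopulationModel] = None,
) -> MonteCarloEstimate:
    if reps < 1:
        raise ValueError("reps must be >= 1")
    # Per-rep child seeds depend only on (seed, rep index), so runs with the
    # same seed are paired across different prevalences and sample sizes.
    seed_rng = np.random.default_rng(seed)
    rep_seeds = seed_rng.integers(0, 2**62, size=(reps, 2))
    template = base_model or PopulationModel(n_specimens=0)
    rejections = 0
    for r in range(reps):
        model_a = replace(
            template,
            n_specimens=n_a,
            prevalence_ct=prevalence_a,
            seed=int(rep_seeds[r, 0]),
        )
        model_b = replace(
            template,
            n_specimens=n_b,
            prevalence_ct=prevalence_b,
            seed=int(rep_seeds[r, 1]),
        )
        ct_a, c7_a = _group_ct_c7(generate_population(model_a))
        ct_b, c7_b = _group_ct_c7(generate_population(model_b))
        if ct_a + c7_a == 0 or ct_b + c7_b == 0:
            continue  # no analyzable specimens; cannot reject
        # strict p < alpha per the significance convention; alpha >= 1 is the
        # degenerate always-reject level (p can equal 1 exactly)
        if alpha >= 1 or _cached_p_two(ct_a, c7_a, ct_b, c7_b) < alpha:
            rejections += 1
    rate_ci: IncidenceResult = incidence(rejections, reps)
    return MonteCarloEstimate(
        rate=rejections / reps,
        ci_low=rate_ci.ci_low,
        ci_high=rate_ci.ci_high,
        reps=reps,
        n_rejections=rejections,
        seed=seed,
    )


def estimate_type1_error(
    model_null: PopulationModel,
    n_a: int,
    n_b: int,
    alpha: float = 0.05,
    reps: int = 2000,
    seed: int = 0,
) -> MonteCarloEstimate:
    """Empirical rejection rate when both groups share model_null's prevalence."""
    if reps < 100:
        raise ValueError("reps must be >= 100 for a type-I error estimate")
    return _rejection_rate(
        prevalence_a=model_null.prevalence_ct,
        prevalence_b=model_null.prevalence_ct,
        n_a=n_a,
        n_b=n_b,
        alpha=alpha,
        reps=reps,
        seed=seed,
        base_model=model_null,
    )


def estimate_power(
    prevalence_a: float,
    prevalence_b: float,
    n_a: int,
    n_b: int,
    alpha: float = 0.05,
    reps: int = 2000,
    seed: int = 0,
    base_model: Optional[PopulationModel] = None,
) -> MonteCarloEstimate:
    """Monte-Carlo power of the exact test for a two-prevalence alternative."""
    if reps < 100:
        raise ValueError("reps must be >= 100 for a power estimate")
    return _rejection_rate(
        prevalence_a=prevalence_a,
        prevalence_b=prevalence_b,
        n_a=n_a,
        n_b=n_b,
        alpha=alpha,
        reps=reps,
        seed=seed,
        base_model=base_model,
    )
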