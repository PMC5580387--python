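import numpy as np
import pytest

from ctvert.characters import CharacterState, SideStates
from ctvert.classifier import (
    CT_THRESHOLD,
    FacetSize,
    Identity,
    IdentityCall,
    SideNotes,
    VertebraRecord,
    asymmetry_flag,
    classify,
    classify_dataset,
    identity_summary,
    rib_facets_present,
)
from ctvert.errors import DuplicateSpecimenError, ProfileError

from conftest import CHARS, make_profile

C, X, T, M = (
    CharacterState.CERVICAL,
    CharacterState.TRANSITIONAL,
    CharacterState.THORACIC,
    CharacterState.MISSING,
)


def record(profile, sid="SPEC-1", **kwargs):
    return VertebraRecord(specimen_id=sid, profile=profile, **kwargs)


class TestRibFacets:
    def test_all_cervical_facets_absent(self, matrix_profiles):
        profile, _ = matrix_profiles["RGM 171525"]  # k, l both cervical
        assert rib_facets_present(profile) is False

    def test_transitional_facets_present(self, matrix_profiles):
        profile, _ = matrix_profiles["RGM 93790"]  # k, l both transitional
        assert rib_facets_present(profile) is True

    def test_any_non_cervical_side_suffices(self):
        assert rib_facets_present({"k": C, "l": T}) is True
        assert rib_facets_present({"k": SideStates(C, X), "l": C}) is True

    def test_both_missing_is_indeterminate(self):
        assert rib_facets_present({"k": M, "l": M}) is None
        assert rib_facets_present({}) is None

    def test_one_missing_one_cervical_is_indeterminate(self):
        # a facet could still hide at the unobserved site
        assert rib_facets_present({"k": C, "l": M}) is None


class TestClassify:
    @pytest.mark.parametrize(
        "sid,n_c,n_x",
        [("RGM 146833", 3, 4), ("RGM 139671", 2, 0), ("RGM 94549", 6, 4)],
    )
    def test_published_count_examples(self, matrix_profiles, sid, n_c, n_x):
        profile, identity = matrix_profiles[sid]
        call = classify(record(profile, sid=sid))
        assert call.identity.value == identity
        assert (call.n_cervical, call.n_transitional) == (n_c, n_x)

    def test_all_matrix_identities(self, matrix_profiles):
        for sid, (profile, identity) in matrix_profiles.items():
            assert classify(record(profile, sid=sid)).identity.value == identity, sid

    def test_all_cervical_is_c7(self):
        call = classify(record(make_profile(c7=CHARS)))
        assert call.identity is Identity.C7
        assert not call.rib_facets_present
        assert call.n_cervical == 12

    def test_exact_threshold_is_ct(self):
        # 6 cervical-or-transitional characters: threshold case is C/T
        profile = make_profile(c7="abcd", ct="kl", t1="efghij")
        call = classify(record(profile))
        assert call.n_cervical + call.n_transitional == CT_THRESHOLD
        assert call.identity is Identity.CT

    def test_below_threshold_is_t1(self):
        profile = make_profile(c7="abc", ct="kl", t1="defghij")
        assert classify(record(profile)).identity is Identity.T1

    def test_indeterminate_when_facets_unscored(self):
        profile = make_profile(c7="abcdefghij")  # k, l missing
        assert classify(record(profile)).identity is Identity.INDETERMINATE

    def test_indeterminate_when_threshold_unreachable(self):
        # facets present, 3 observed cervical, 5 missing: could be 3..8
        profile = make_profile(c7="abc", t1="klde")
        call = classify(record(profile))
        assert call.n_missing == 5
        assert call.identity is Identity.INDETERMINATE

    def test_t1_when_missing_cannot_rescue(self):
        # facets present, 1 cervical, 2 missing: at most 3 < 6
        profile = make_profile(c7="a", t1="defghijkl")
        call = classify(record(profile))
        assert call.n_missing == 2
        assert call.identity is Identity.T1

    def test_invalid_profile_raises(self):
        with pytest.raises(ProfileError):
            classify(record({"z": C}))

    def test_counts_always_sum_to_twelve(self, matrix_profiles):
        for sid, (profile, _) in matrix_profiles.items():
            call = classify(record(profile, sid=sid))
            total = (
                call.n_cervical + call.n_transitional + call.n_thoracic + call.n_missing
            )
            assert total == 12

    def test_identity_call_invariants_enforced(self):
        with pytest.raises(ValueError):
            IdentityCall(Identity.CT, 6, 0, 6, 0, rib_facets_present=False, asymmetric=False)
        with pytest.raises(ValueError):
            IdentityCall(Identity.C7, 12, 0, 0, 0, rib_facets_present=True, asymmetric=False)
        with pytest.raises(ValueError):
            IdentityCall(Identity.C7, 5, 0, 0, 0, rib_facets_present=False, asymmetric=False)


class TestThresholdSharpness:
    """Brute-force check of the step at 6 over complete profiles."""

    STATES = (C, X, T)

    def sample_profiles(self, rng, n):
        for _ in range(n):
            yield {ch: self.STATES[i] for ch, i in zip(CHARS, rng.integers(0, 3, 12))}

    def boundary_profiles(self, rng, per_count=400):
        # profiles engineered to sit just at or below the threshold count
        for count in (CT_THRESHOLD - 1, CT_THRESHOLD):
            for _ in range(per_count):
                ids = list(CHARS)
                rng.shuffle(ids)
                chosen = ids[:count]
                profile = {}
                for ch in CHARS:
                    if ch in chosen:
                        profile[ch] = self.STATES[rng.integers(0, 2)]  # C or X
                    else:
                        profile[ch] = T
                yield profile

    def test_step_at_six(self):
        rng = np.random.default_rng(42)
        profiles = list(self.sample_profiles(rng, 10_000)) + list(
            self.boundary_profiles(rng)
        )
        for profile in profiles:
            call = classify(record(profile))
            count = call.n_cervical + call.n_transitional
            facets = profile["k"] is not C or profile["l"] is not C
            if facets:
                expected = Identity.CT if count >= CT_THRESHOLD else Identity.T1
            else:
                expected = Identity.C7
            assert call.identity is expected

    def test_flip_thoracic_to_cervical_never_demotes(self):
        rng = np.random.default_rng(7)
        for profile in self.sample_profiles(rng, 2_000):
            if profile["k"] is C and profile["l"] is C:
                continue
            before = classify(record(profile))
            thoracic_ids = [
                ch for ch in CHARS if profile[ch] is T and ch not in ("k", "l")
            ]
            if not thoracic_ids:
                continue
            flipped = dict(profile)
            flipped[thoracic_ids[0]] = C
            after = classify(record(flipped))
            count_before = before.n_cervical + before.n_transitional
            count_after = after.n_cervical + after.n_transitional
            assert count_after >= count_before
            if before.identity is Identity.CT:
                assert after.identity is Identity.CT


class TestAsymmetry:
    def test_side_note_size_difference(self):
        rec = record(
            make_profile(c7=CHARS),
            side_notes=SideNotes(
                facet_left=FacetSize.SMALL,
                facet_right=FacetSize.LARGE,
                position_note="left facet more dorsal",
            ),
        )
        assert asymmetry_flag(rec) is True

    def test_identical_sides_everywhere(self):
        profile = make_profile(c7="abcdeg", t1="")
        profile.update({ch: SideStates(C, C) for ch in "fhijkl"})
        rec = record(
            profile,
            side_notes=SideNotes(facet_left=FacetSize.NONE, facet_right=FacetSize.NONE),
        )
        assert asymmetry_flag(rec) is False

    def test_discordant_bilateral_states(self):
        profile = make_profile(c7="abcdeghij")
        profile["k"] = SideStates(C, T)
        profile["l"] = C
        assert asymmetry_flag(record(profile)) is True

    def test_no_side_information_defaults_false(self):
        assert asymmetry_flag(record(make_profile(c7=CHARS))) is False

    def test_fixture_asymmetric_specimens(self, matrix_records):
        calls = classify_dataset(matrix_records)
        flagged = set(calls.index[calls["asymmetric"]])
        assert flagged == {"RGM 94549", "RGM 445933", "RGM 93790"}


class TestClassifyDataset:
    def test_matrix_summary(self, matrix_records):
        calls = classify_dataset(matrix_records)
        assert identity_summary(calls) == {
            "C7": 3,
            "C/T": 5,
            "T1": 4,
            "indeterminate": 0,
        }
        assert calls.attrs["summary"]["C/T"] == 5

    def test_fossil_summary(self, fossil_records):
        summary = identity_summary(classify_dataset(fossil_records))
        assert summary["C/T"] == 5
        assert summary["C7"] == 27

    def test_order_preserved(self, matrix_records):
        calls = classify_dataset(matrix_records)
        assert list(calls.index) == [r.specimen_id for r in matrix_records]

    def test_deterministic(self, matrix_records):
        a = classify_dataset(matrix_records)
        b = classify_dataset(matrix_records)
        assert a.equals(b)

    def test_duplicate_id_raises(self):
        recs = [record(make_profile(c7=CHARS), sid="A")] * 2
        with pytest.raises(DuplicateSpecimenError, match="A"):
            classify_dataset(recs)

    def test_empty_input(self):
        calls = classify_dataset([])
        assert len(calls) == 0
        assert identity_summary(calls) == {
            "C7": 0,
            "C/T": 0,
            "T1": 0,
            "indeterminate": 0,
        }

    def test_ct_calls_always_have_facets(self, fossil_records, matrix_records):
        for recs in (fossil_records, matrix_records):
            calls = classify_dataset(recs)
            assert calls.loc[calls.identity == "C/T", "rib_facets_present"].all()
            assert not calls.loc[calls.identity == "C7", "rib_facets_present"].any()
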