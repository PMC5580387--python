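import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from ctvert.characters import CharacterState
from ctvert.datasets import load_fixture

C = CharacterState.CERVICAL
X = CharacterState.TRANSITIONAL
T = CharacterState.THORACIC
M = CharacterState.MISSING

CHARS = "abcdefghijkl"

#: The published specimen x character matrix: letters per column plus the
#: printed identity call, used as a regression target throughout the suite.
MATRIX_ROWS = {
    "RGM 139671": ("fh", "", "abcdegijkl", "T1"),
    "RGM 146833": ("bde", "fjkl", "ag", "C/T"),
    "RGM 171525": ("abeghijkl", "df", "", "C7"),
    "RGM 369367": ("abcdeghijkl", "f", "", "C7"),
    "RGM 369657": ("abefghijkl", "d", "", "C7"),
    "RGM 445933": ("bdegj", "fl", "ak", "C/T"),
    "RGM 55336": ("", "f", "abcdegjkl", "T1"),
    "RGM 93477": ("cg", "aefj", "bdkl", "C/T"),
    "RGM 93479": ("f", "", "abcdeghijkl", "T1"),
    "RGM 93485": ("e", "", "adfgjkl", "T1"),
    "RGM 93790": ("e", "acdfjkl", "bg", "C/T"),
    "RGM 94549": ("cefghi", "bdjl", "ak", "C/T"),
}


def make_profile(c7="", ct="", t1=""):
    profile = {}
    for letters, state in ((c7, C), (ct, X), (t1, T)):
        for ch in letters:
            profile[ch] = state
    for ch in CHARS:
        profile.setdefault(ch, M)
    return profile


@pytest.fixture(scope="session")
def matrix_profiles():
    return {
        sid: (make_profile(c7, ct, t1), identity)
        for sid, (c7, ct, t1, identity) in MATRIX_ROWS.items()
    }


@pytest.fixture(scope="session")
def matrix_records():
    return load_fixture("table4_matrix")


@pytest.fixture(scope="session")
def fossil_records():
    return load_fixture("coelodonta_c7")


@pytest.fixture(scope="session")
def extant_records():
    return load_fixture("extant_rhino")
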