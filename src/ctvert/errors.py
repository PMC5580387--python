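"""Exception hierarchy shared across the package."""


class CtvertError(Exception):
    """Base class for all package errors."""


class UnsupportedCharacterError(CtvertError):
    """A quantitative operation was requested for a non-quantitative character."""


class InvalidMeasurementError(CtvertError):
    """A raw measurement violates its domain (non-positive length, bad ratio)."""


class ProfileError(CtvertError):
    """A character profile is structurally invalid beyond mere findings."""


class DuplicateSpecimenError(CtvertError):
    """Two records in one dataset share a specimen id."""

    def __init__(self, specimen_id: str):
        self.specimen_id = specimen_id
        super().__init__(f"duplicate specimen id: {specimen_id!r}")


class SpecimenTableError(CtvertError):
    """A specimen table file failed to parse; carries per-line messages."""

    def __init__(self, problems: list[str]):
        self.problems = list(problems)
        super().__init__("; ".join(self.problems))


class UndefinedStatisticError(CtvertError):
    """A statistic is undefined for the given inputs (e.g. zero denominator)."""
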