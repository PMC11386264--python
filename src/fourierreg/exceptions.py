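"""Exception hierarchy for fourierreg."""


class FourierRegError(Exception):
    """Base class for all fourierreg errors."""


class SpecificationError(FourierRegError):
    """A model specification is invalid (bad oscillation counts, shape mismatch)."""


class InputDataError(FourierRegError):
    """Input data is unusable (non-finite values, missing columns, bad CSV)."""


class SaturatedModelError(FourierRegError):
    """The design has no residual degrees of freedom (rank >= n)."""


class EstimabilityError(FourierRegError):
    """A requested constraint direction is not estimable."""


class SearchBudgetError(FourierRegError):
    """A combination search would exceed its candidate budget."""
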