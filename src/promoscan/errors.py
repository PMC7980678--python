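"""Exception hierarchy for promoscan.

All errors derive from :class:`PromoscanError`; validation errors that are
really bad values also derive from :class:`ValueError` so generic callers can
catch them idiomatically.
"""


class PromoscanError(Exception):
    """Base class for all promoscan errors."""


class SchemaError(PromoscanError):
    """An input table is missing a required column or has a malformed header."""


class IntegrityError(PromoscanError, ValueError):
    """A table violates a data invariant (duplicate key, nonpositive value, bad enum)."""


class ConfigError(PromoscanError, ValueError):
    """A configuration object holds an out-of-range or infeasible value."""


class ContractError(PromoscanError, ValueError):
    """A function was called outside its documented precondition."""


class SingularDesignError(PromoscanError):
    """The regression design matrix is rank deficient.

    Carries ``columns``: the names of the offending (linearly dependent)
    columns.
    """

    def __init__(self, columns):
        self.columns = list(columns)
        super().__init__(
            "design matrix is singular; linearly dependent columns: "
            + ", ".join(self.columns)
        )


class ConsistencyError(PromoscanError):
    """Recomputed exposure disagrees with the generator's planted truth."""
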