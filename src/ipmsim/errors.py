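"""Exception hierarchy.

The CLI maps :class:`ConfigError` / :class:`DatasetError` to exit code 2
(validation failure) and :class:`NumericalError` (including singular
designs) to exit code 3.
"""


class IPMError(Exception):
    """Base class for all package errors."""


class ConfigError(IPMError):
    """Invalid process definition, model assignment or run configuration."""


class DatasetError(IPMError):
    """Malformed or inconsistent tabular dataset."""


class NumericalError(IPMError):
    """Numerical failure during fitting or simulation."""


class SingularDesignError(NumericalError):
    """Rank-deficient model matrix; carries the aliased term labels."""

    def __init__(self, aliased: list[str]):
        self.aliased = list(aliased)
        super().__init__(
            "singular design matrix; aliased terms: " + ", ".join(self.aliased)
        )
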