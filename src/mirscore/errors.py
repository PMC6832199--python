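"""Exception hierarchy shared by all pipeline stages.

Exit-code mapping used by the CLI: SchemaError -> 2, DegenerateInputError -> 3,
ConfigError -> 4.  All inherit from :class:`InputError` (a ``ValueError``).
"""


class InputError(ValueError):
    """Invalid input to an operation (wrong shape, empty group, bad value)."""


class SchemaError(InputError):
    """A cohort file violates the expected schema or a record invariant."""


class DegenerateInputError(InputError):
    """Statistically degenerate input: single-class labels, constant covariate."""


class ConfigError(InputError):
    """Invalid simulation or pipeline configuration."""
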