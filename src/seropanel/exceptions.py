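"""Exception types shared across the package."""


class ConfigurationError(ValueError):
    """An invalid configuration value (counts, probabilities, fractions...)."""


class CohortValidationError(ValueError):
    """A cohort table violates the subject-level schema."""
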