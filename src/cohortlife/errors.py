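"""Exception types shared across the pipeline."""


class CohortError(ValueError):
    """Unrecoverable problem with cohort input data or preprocessing."""


class LifeTableError(ValueError):
    """Life table cannot be built from the supplied exposure."""


class ConfigError(ValueError):
    """Invalid run or simulation configuration."""
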