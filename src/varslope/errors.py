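"""Exception types shared across the pipeline."""


class ConfigurationError(ValueError):
    """Invalid configuration or arguments (bad ranges, mismatched lengths)."""


class ProcessingError(RuntimeError):
    """Input data cannot be processed (all-missing leg, no filtered periods)."""
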