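"""Exception types shared across the pipeline."""


class ConfigurationError(ValueError):
    """An invalid paradigm, montage, simulation or training configuration."""


class AlignmentError(ValueError):
    """Two data structures that must share an axis (epochs, windows) do not."""
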