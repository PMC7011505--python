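"""Exception hierarchy for the kd2 toolkit."""


class KD2Error(Exception):
    """Base class for all kd2-specific errors."""


class ConfigurationError(KD2Error):
    """Inconsistent or invalid parameters (window sizes, metadata mismatch)."""


class DegenerateRegionError(KD2Error):
    """A region of interest carries (numerically) zero mass.

    Raised instead of emitting NaN descriptors so that blank background
    windows fail loudly and never enter an index.
    """


class GenerationError(KD2Error):
    """Synthetic fixture generation could not satisfy its own constraints."""
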