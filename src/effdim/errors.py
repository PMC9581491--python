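"""Exception types shared across the package."""


class EffdimError(Exception):
    """Base class for package-specific errors."""


class DegenerateOutputError(EffdimError):
    """The model output has zero pooled variance; sensitivity indices are undefined."""


class NearZeroMeanError(EffdimError):
    """The output mean is too close to zero for the coefficient of variation
    to be a meaningful dispersion measure; consider sd/IQR instead."""


class MissingSubsetError(EffdimError, KeyError):
    """A requested parameter subset has no swapped matrix in the design."""


class ChainSpecError(EffdimError):
    """A compartmental chain declaration is inconsistent."""


class IntegrationError(EffdimError):
    """The ODE solver failed; carries solver diagnostics in the message."""


class ConfigError(EffdimError):
    """A run configuration failed schema validation."""
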