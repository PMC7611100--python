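"""Exception hierarchy for selearn."""


class SelearnError(Exception):
    """Base class for all selearn errors."""


class ConfigurationError(SelearnError):
    """Invalid task or population configuration (e.g. probability outside [0, 1])."""


class ParameterError(SelearnError):
    """Invalid model parameter (e.g. non-positive decision noise, NaN)."""


class ModelError(SelearnError):
    """An agent or model produced an invalid quantity (e.g. probability outside [0, 1])."""


class ValidationError(SelearnError):
    """Data violates a structural invariant (e.g. inconsistent feedback column)."""


class FormatError(SelearnError):
    """A file does not conform to the expected on-disk format."""


class DegenerateBeliefError(SelearnError):
    """A belief with zero total evidence was used where a defined mean is required."""


class OptimizationError(SelearnError):
    """Maximum-likelihood optimisation failed on every restart."""


class ComparisonError(SelearnError):
    """Model-comparison inputs are incompatible (e.g. fits on different data)."""
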