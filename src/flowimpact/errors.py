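"""Exception hierarchy for the flowimpact pipeline.

Each stage raises a subclass of :class:`FlowImpactError` so that callers
(and the command-line driver) can report which stage failed.
"""


class FlowImpactError(Exception):
    """Base class for all package errors."""


class ConfigError(FlowImpactError):
    """Invalid scenario or run configuration."""


class GenerationError(FlowImpactError):
    """Synthetic-data generation failed (e.g. log-intensity overflow)."""


class AlignmentError(FlowImpactError):
    """Input series do not share a common, gapless monthly index."""


class ValidationError(FlowImpactError):
    """Input data violates a structural invariant (negative counts, ...)."""


class ImputationError(FlowImpactError):
    """Missing-value imputation cannot proceed (e.g. all values missing)."""


class NumericError(FlowImpactError):
    """A numerical routine received non-finite input or hit a singularity."""


class SamplerError(FlowImpactError):
    """The MCMC sampler produced non-finite draws."""


class AnalysisError(FlowImpactError):
    """The counterfactual analysis pre-conditions are not met."""
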