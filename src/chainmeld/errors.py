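"""Exception hierarchy for chainmeld.

All chainmeld-specific failures derive from :class:`ChainMeldError` so that
callers can catch library errors without masking programming mistakes.
"""


class ChainMeldError(Exception):
    """Base class for all chainmeld errors."""


class InvalidWeightsError(ChainMeldError):
    """A pooling weight is negative or otherwise inadmissible."""


class DegeneratePoolingError(ChainMeldError):
    """All pooling weights are zero (or a mixture pair sums to zero)."""


class SupportMismatchError(ChainMeldError):
    """A submodel prior marginal is zero where the pooled prior places mass."""


class ImproperPooledPriorError(ChainMeldError):
    """Closed-form pooling produced a non-integrable (non-PD) result."""


class LayoutError(ChainMeldError):
    """Dimension or slot mismatch against the shared-quantity layout."""


class ChainValidationError(ChainMeldError):
    """A chain of submodels violates the adjacency/slot contract."""


class RankDeficiencyError(ChainMeldError):
    """Sample covariance of draws is singular; no Gaussian summary exists."""


class ImproperCorrectionError(ChainMeldError):
    """The precision difference in the Gaussian correction is not PD."""


class InitialisationError(ChainMeldError):
    """A sampler could not be initialised at a finite log-density point."""


class ProposalSupportError(ChainMeldError):
    """A proposal density is zero at the current point."""


class InvalidStateError(ChainMeldError):
    """The sampler's current state has zero target density."""


class ConfigError(ChainMeldError):
    """A run configuration is missing required keys or is inconsistent."""
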