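"""Exception hierarchy.

Every precondition violation named in the public API raises a distinct
subclass of :class:`RareSphereError` so callers can discriminate without
string matching.
"""


class RareSphereError(Exception):
    """Base class for all raresphere errors."""


class TableParseError(RareSphereError):
    """A tabular input file could not be parsed (bad column count/type)."""


class NonPositiveCountError(RareSphereError):
    """An OTU abundance of zero or less was encountered."""


class DuplicateOTUError(RareSphereError):
    """The same OTU id appeared more than once in an abundance table."""


class RichnessBelowObservedError(RareSphereError):
    """A total richness S below the observed richness was requested."""


class QuadratureError(RareSphereError):
    """Numerical integration of a mixed-Poisson pmf failed to converge."""


class ProposalDegenerateError(RareSphereError):
    """An MCMC proposal scale produced zero acceptances over burn-in."""


class RichnessCapError(RareSphereError):
    """The richness cap s_max was binding for more than 1% of MCMC draws."""


class ACEUndefinedError(RareSphereError):
    """ACE sample coverage is zero (all rare reads are singletons)."""


class CoverageLengthError(RareSphereError):
    """A match record lacks the isolate length needed for coverage."""


class HorizonTooSmallError(RareSphereError):
    """Every effort simulation was censored at the simulation horizon."""


class AICcUndefinedError(RareSphereError):
    """AICc denominator n - k - 1 is not positive."""
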