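"""Package-specific error types.

All inherit from ValueError so that callers who only care about "bad input"
can catch one base class.
"""


class LatticeConfigError(ValueError):
    """Invalid lattice dimensions or an incompatible topology/lattice pair."""


class OutOfBoundsError(ValueError):
    """A site lies outside the lattice (before periodic wrap is applied)."""


class NotSpatialError(ValueError):
    """A spatial operation was requested under the panmictic (gnf) scheme."""


class DegenerateSampleError(ValueError):
    """A fit was requested on a sample with no usable dispersion."""


class NoDecayError(ValueError):
    """Heterozygosity series shows no decay; effective size is unbounded."""


class AllRunsCappedError(ValueError):
    """Every replicate hit the generation cap; T_ave is undefined."""


class UndefinedInbreedingError(ValueError):
    """Inbreeding coefficient requested for a fixed population (f in {0,1})."""
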