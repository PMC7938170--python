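"""Exception types raised by the simulator."""


class BicellError(Exception):
    """Base class for all package-specific errors."""


class InvalidGenotypeError(BicellError, ValueError):
    """A genotype violates its invariants (non-finite genes, bad viability vector, ...)."""


class UndefinedStatisticError(BicellError, ValueError):
    """A summary statistic was requested on an empty population or trajectory."""


class ExtinctionError(BicellError, RuntimeError):
    """The population went extinct while the engine expected living individuals."""
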