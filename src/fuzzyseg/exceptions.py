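"""Exception hierarchy.

Two broad families matter to callers: data/format problems (bad files,
inconsistent shapes) and numerical/degeneracy problems (coincident centers,
empty clusters, constant images). The CLI maps them to distinct exit codes.
"""


class FuzzySegError(Exception):
    """Base class for all package errors."""


class DataFormatError(FuzzySegError):
    """Malformed or inconsistent input data (files, shapes, tables)."""


class DimensionError(DataFormatError):
    """Array shapes are mutually inconsistent."""


class NumericalError(FuzzySegError):
    """A computation cannot proceed for numerical/degeneracy reasons."""


class DegenerateClusterError(NumericalError):
    """A cluster has zero total membership (violates the row-sum constraint)."""


class DegenerateCentersError(NumericalError):
    """Two or more cluster centers coincide."""


class DegenerateRangeError(NumericalError):
    """The image is constant over the mask; min-max normalization undefined."""


class InfeasibleError(NumericalError):
    """Fewer distinct intensities than requested clusters."""


class DomainError(NumericalError):
    """A value lies outside its mathematically required domain."""
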