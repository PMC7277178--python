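"""Exception hierarchy for validation and pipeline failures."""


class MCDAError(Exception):
    """Base class for all package errors."""


class HierarchyError(MCDAError):
    """Invalid criteria hierarchy document."""


class DuplicateIdError(HierarchyError):
    pass


class OrphanNodeError(HierarchyError):
    pass


class DepthError(HierarchyError):
    pass


class LeafAttributeError(HierarchyError):
    """Leaf missing direction/data kind, or internal node carrying them."""


class MatrixError(MCDAError):
    """Invalid pairwise comparison matrix."""


class ConvergenceError(MCDAError):
    """Power iteration failed to converge within the iteration cap."""


class EncodingError(MCDAError):
    """A raw score cell could not be fuzzified."""


class TableError(MCDAError):
    """Invalid performance table or binding failure against the hierarchy."""


class NormalizationError(MCDAError):
    """Zero/negative divisor while normalizing a column; pre-shift the data."""


class ConfigError(MCDAError):
    """Invalid run configuration."""


class ConsistencyError(MCDAError):
    """Consistency ratio above threshold under strict-CR policy."""
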