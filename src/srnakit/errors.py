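"""Exception hierarchy shared across the package."""


class SrnaKitError(Exception):
    """Base class for all srnakit errors."""


class ValidationError(SrnaKitError, ValueError):
    """Invalid domain object (bad residues, bad labels, bad interval)."""


class FastaParseError(SrnaKitError, ValueError):
    """Structurally malformed FASTA input."""


class RangeError(SrnaKitError, ValueError):
    """Genomic interval outside the sequence bounds."""


class ConfigError(SrnaKitError, ValueError):
    """Invalid parameter combination (k, m, lambda, ratio, GA settings...)."""


class LengthError(SrnaKitError, ValueError):
    """Sequence too short for the requested encoder."""


class TableError(SrnaKitError, ValueError):
    """Physicochemical property table incomplete or inconsistent."""


class DegeneratePropertyError(TableError):
    """A property column is constant and cannot be standardized."""


class TrainingError(SrnaKitError, ValueError):
    """Training data unusable (e.g. a single class)."""


class StateError(SrnaKitError, RuntimeError):
    """Operation on a model that is not in the required state (e.g. unfitted)."""


class SplitError(SrnaKitError, ValueError):
    """Cross-validation split impossible (class smaller than fold count)."""


class LeakageError(SrnaKitError, RuntimeError):
    """Train/test contamination detected by the cross-validation guard."""
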