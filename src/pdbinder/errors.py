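"""Exception hierarchy shared across the package."""


class PDBinderError(Exception):
    """Base class for all package-specific errors."""


class EmptyStructureError(PDBinderError):
    """A parsed file contains no standard protein residues."""


class IncompleteResidueError(PDBinderError):
    """A residue lacks an atom required by the representation scheme."""


class InvalidLigandError(PDBinderError):
    """A ligand record violates a precondition (e.g. zero heavy atoms)."""


class ConfigurationError(PDBinderError):
    """Inconsistent or incomplete run configuration."""


class EmptyLibraryError(PDBinderError):
    """The filter pipeline discarded every chain/residue."""


class GeometryError(PDBinderError):
    """A synthetic-geometry request could not be satisfied."""


class UndefinedMetricError(PDBinderError):
    """A metric (e.g. AUC on a single-class sample) is undefined."""
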