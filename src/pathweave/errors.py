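"""Exception hierarchy shared across the package."""


class PathweaveError(Exception):
    """Base class for all package-specific errors."""


class InputError(PathweaveError):
    """A user-supplied file is missing, empty, or malformed."""


class GeneListParseError(InputError):
    """A gene-list line could not be parsed; the message names the line."""


class EmptyStoreError(InputError):
    """The annotation source contains no rows for the requested organism."""


class EmptyIntersectionError(InputError):
    """No input gene is present in the annotation background."""


class DomainError(PathweaveError):
    """A numeric argument violates the bounds of the statistic."""


class KGMLParseError(PathweaveError):
    """The KGML document is malformed or missing required attributes."""


class SBMLError(PathweaveError):
    """An SBML document could not be read or violates network invariants."""
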