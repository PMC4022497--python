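"""Exception hierarchy shared across the package.

The CLI maps these onto exit codes: :class:`InputError` -> 2,
:class:`DegenerateDataError` and subclasses -> 3.
"""


class EcrError(Exception):
    """Base class for all package errors."""


class InputError(EcrError):
    """Unreadable, malformed or inconsistent user input."""


class EmptyStructureError(InputError):
    """A structure file contained no usable protein residues."""


class DegenerateDataError(EcrError):
    """Data is syntactically valid but unusable for the requested computation."""


class InsufficientDataError(DegenerateDataError):
    """Fewer usable observations than the operation requires."""


class DegenerateGeometryError(DegenerateDataError):
    """Coordinate configuration without the variation the operation needs."""


class FeatureMismatchError(InputError):
    """Feature names/order of a matrix do not match a trained model."""
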