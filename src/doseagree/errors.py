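"""Exception hierarchy shared by all doseagree modules."""


class DoseAgreeError(Exception):
    """Base class for all doseagree errors."""


class FormatError(DoseAgreeError):
    """A file could not be parsed; the message names the offending line."""


class ValidationError(DoseAgreeError, ValueError):
    """An object violates a domain invariant (negative dose, zero spacing, ...)."""


class GeometryError(DoseAgreeError):
    """Grids are spatially incompatible (evaluated point outside reference extent,
    shift pushing the field off the grid, misaligned lattices)."""


class DegenerateInputError(DoseAgreeError):
    """Input is structurally valid but the operation is undefined on it
    (all-zero grid, empty evaluation mask, single-row gradient)."""


class UnsupportedCriteriaError(DoseAgreeError):
    """Requested criteria outside the tabulated divide-and-conquer rows."""
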