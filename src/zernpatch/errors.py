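"""Exception hierarchy for the patch-complementarity pipeline.

Every stage raises a subclass of :class:`ZernpatchError`, so callers (and
the CLI) can distinguish user-input problems from geometry degeneracies.
"""


class ZernpatchError(Exception):
    """Base class for all package errors."""


class StructureParseError(ZernpatchError):
    """The structure file could not be read or contains no usable records."""


class EmptyStructureError(ZernpatchError):
    """No protein heavy atoms remain after filtering."""


class SelectionError(ZernpatchError):
    """Chain selection refers to missing chains or overlapping partner sets."""


class NoInterfaceError(ZernpatchError):
    """No surface points of the two partners fall within the contact cutoff."""


class DegeneratePatchError(ZernpatchError):
    """A surface patch has too few points to support a stable expansion."""


class OrientationError(ZernpatchError):
    """The mean normal of a patch vanishes; the patch cannot be oriented."""


class ConeFitError(ZernpatchError):
    """No cone vertex on the z-axis contains the patch at the requested angle."""


class DescriptorMismatchError(ZernpatchError):
    """Two descriptors with different orders or index sets were compared."""


class DecoySamplingError(ZernpatchError):
    """Too many decoy patches failed; the surface is too small for the radius."""
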