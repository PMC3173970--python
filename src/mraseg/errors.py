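"""Exception hierarchy shared across the package.

All errors derive from :class:`MRASegError` so callers can catch one base
type; the concrete classes also derive from the closest builtin so that
idiomatic ``except ValueError`` style code keeps working.
"""


class MRASegError(Exception):
    """Base class for every error raised by this package."""


class ParameterError(MRASegError, ValueError):
    """An argument value is outside its documented domain."""


class ShapeMismatchError(MRASegError, ValueError):
    """Two arrays that must share a shape do not."""


class FormatError(MRASegError, ValueError):
    """An image file is readable but not in a supported format."""


class RangeError(MRASegError, ValueError):
    """Intensities do not fit the requested output bit depth."""


class GeometryError(MRASegError, ValueError):
    """A phantom specification describes impossible geometry."""


class StructureError(MRASegError, ValueError):
    """A coefficient container is internally inconsistent."""
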