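"""Exception hierarchy shared across the package."""


class ContourQAError(Exception):
    """Base class for all package-specific errors."""


class ParseError(ContourQAError):
    """A file did not conform to its documented dialect."""


class GridMismatchError(ContourQAError):
    """Two objects that must share an :class:`ImageGrid` do not."""


class EmptyMaskError(ContourQAError):
    """An operation that requires occupied voxels received an empty mask."""


class PolicyError(ContourQAError):
    """A structure has no entry in the dose-metric policy."""
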