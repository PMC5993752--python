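"""Exception hierarchy shared across the pipeline stages."""


class FundusError(Exception):
    """Base class for all package-specific errors."""


class InvalidSpecificationError(FundusError, ValueError):
    """A generator or filter specification is out of its valid domain."""


class InvalidInputError(FundusError, ValueError):
    """An input raster/segment violates a stage precondition."""


class DegenerateInputError(FundusError, ValueError):
    """Input is formally valid but degenerate for the requested method
    (e.g. Otsu on a constant image, zero green mean)."""


class ImageIOError(FundusError, OSError):
    """File could not be read/written as a 3-channel image."""


class UndefinedTortuosityError(FundusError, ValueError):
    """Arc/chord tortuosity is undefined (coincident endpoints)."""


class IncompleteReportError(FundusError, ValueError):
    """A metric report cannot be assembled because a vessel class is absent."""
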