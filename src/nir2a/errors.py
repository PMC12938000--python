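"""Exception types shared across the pipeline."""


class Nir2aError(Exception):
    """Base class for all package errors."""


class ValidationError(Nir2aError):
    """A value or configuration violates a documented invariant."""


class DivisibilityError(ValidationError):
    """Image dimensions do not satisfy the divisible-by-40 contract
    (three stride-2 convolutions followed by 5x5 patching)."""


class UnsupportedFormatError(Nir2aError):
    """Image file is not 8/16-bit single-channel TIFF or PNG."""


class ROIPlacementError(Nir2aError):
    """Automatic ROI placement could not satisfy its constraints."""


class ProfileError(Nir2aError):
    """A line profile does not contain a resolvable peak."""
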