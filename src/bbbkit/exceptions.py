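"""Exception and warning types shared across the package."""


class BBBKitError(Exception):
    """Base class for all bbbkit errors."""


class InvalidInputError(BBBKitError, ValueError):
    """Input violates an operation's preconditions."""


class InvalidPairingError(BBBKitError, ValueError):
    """Two ranked vectors were not ranked in the same joint pool."""


class SegmentationError(BBBKitError, RuntimeError):
    """Vessel or brain segmentation produced no usable mask."""


class RegistrationError(BBBKitError, RuntimeError):
    """Image registration failed for a named frame or scan."""


class WindowNotFoundError(BBBKitError, RuntimeError):
    """No post-peak sample satisfies the clearance derivative band."""


class DivisionGuardError(BBBKitError, ZeroDivisionError):
    """A denominator curve is zero or negative where a ratio is required."""


class DegenerateNullWarning(UserWarning):
    """The sham null has zero spread; the 3-SD rule degenerates to the mean."""


class DegenerateHistogramWarning(UserWarning):
    """A compartment histogram occupies a single intensity bin."""


class RegistrationFallbackWarning(UserWarning):
    """Registration quality was too poor to trust; identity transform used."""


class FlatSpectrumWarning(UserWarning):
    """Spectrum has no unique maximum; dominant frequency tie-broken low."""
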