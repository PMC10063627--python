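"""Exception hierarchy for slimloc."""


class SlimlocError(Exception):
    """Base class for all slimloc errors."""


class GeometryError(SlimlocError):
    """Invalid microphone-array geometry or microphone pair."""


class InvalidPairError(GeometryError):
    """A microphone pair referenced with identical or out-of-range indices."""


class InfeasibleDelayError(SlimlocError):
    """A time delay implying a path difference >= the inter-microphone distance."""


class DegenerateSignalError(SlimlocError):
    """An all-zero or otherwise degenerate analysis window."""


class NoDelayError(SlimlocError):
    """No physically feasible correlation peak in a window."""


class InsufficientPairsError(SlimlocError):
    """Fewer than two origin curves available for intersection."""


class FeatureExtractionError(SlimlocError):
    """A segment without usable in-band energy."""


class MissingTrackError(SlimlocError):
    """Tracking markers missing for a required animal or frame."""


class InvalidAccuracyError(SlimlocError):
    """A non-positive localization-accuracy value where one is required."""


class IncompatibleMapsError(SlimlocError):
    """Polar maps with mismatching bin edges."""


class ValidationError(SlimlocError):
    """Invalid input data (non-finite values, bad shapes, bad parameters)."""


class AudioFormatError(SlimlocError):
    """Unreadable or inconsistent audio files."""
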