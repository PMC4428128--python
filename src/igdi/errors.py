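"""Exception hierarchy shared across the package.

Everything derives from :class:`IgdiError` so callers can catch the
package's own failures without swallowing genuine bugs.
"""


class IgdiError(Exception):
    """Base class for all errors raised by this package."""


class GazeFormatError(IgdiError, ValueError):
    """A gaze/markers/scores table is malformed (e.g. a required column is missing)."""


class EmptyInputError(IgdiError, ValueError):
    """An input file or matrix contains no data."""


class EmptyEpochError(IgdiError, ValueError):
    """Epoching a stream against its markers selected no samples."""


class GridMismatchError(IgdiError, ValueError):
    """The window grid does not fit inside the common stream duration."""


class ContractError(IgdiError, ValueError):
    """Two aligned containers disagree in length or mode."""


class NullDegeneracyError(IgdiError, ValueError):
    """Too few usable windows to randomize the Monte-Carlo null over."""


class UndefinedIndexError(IgdiError, ValueError):
    """A divergence index is undefined (zero usable windows)."""


class DegeneratePredictorError(IgdiError, ValueError):
    """The regression predictor is constant; the slope is undefined."""


class JoinError(IgdiError, ValueError):
    """Two tables could not be joined on video id; offenders are listed."""


class InsufficientBeatsError(IgdiError, ValueError):
    """Fewer than two inter-beat intervals; RMSSD is undefined."""


class UndefinedChangeError(IgdiError, ValueError):
    """Baseline RMSSD is zero; percent change is undefined."""


class InsufficientSignalError(IgdiError, ValueError):
    """Too few heart-beat peaks were detected in the waveform."""


class ConstantInputError(IgdiError, ValueError):
    """A correlation input is constant; the coefficient is undefined."""
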