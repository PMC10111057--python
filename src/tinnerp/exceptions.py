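"""Exception hierarchy shared across the package."""


class TinnerpError(Exception):
    """Base class for all package-specific errors."""


class MissingDataError(TinnerpError):
    """A required clinical field (tinnitus profile, audiogram, session) is absent."""


class MissingChannelError(TinnerpError):
    """A required EEG channel is not present in the recording montage."""


class EligibilityError(TinnerpError):
    """The participant does not meet the eligibility rule of the requested therapy."""


class IncompatibleAxesError(TinnerpError):
    """Two waveform sets do not share montage, sampling rate or time axis."""


class EmptyEpochsError(TinnerpError):
    """No usable epochs could be extracted from the recording."""


class InsufficientSampleError(TinnerpError):
    """Sample size below the validity floor of a statistical test."""


class DegenerateDataError(TinnerpError):
    """Input data are degenerate (e.g. constant) and the statistic is undefined."""
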