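"""Exception hierarchy for the kcindex pipeline.

All pipeline errors derive from :class:`KCIndexError` so callers can
distinguish data problems from programming errors.
"""


class KCIndexError(Exception):
    """Base class for all kcindex pipeline errors."""


class FormatError(KCIndexError):
    """A recording file violates the on-disk format contract."""


class MissingLimbError(KCIndexError):
    """A subject is missing one of the four limb recordings."""

    def __init__(self, limb_id: str):
        self.limb_id = limb_id
        super().__init__(f"missing limb recording: {limb_id}")


class InsufficientOverlapError(KCIndexError):
    """The four limb recordings overlap for less than the required duration."""

    def __init__(self, overlap_s: float, required_s: float):
        self.overlap_s = overlap_s
        self.required_s = required_s
        super().__init__(
            f"limb recordings overlap for {overlap_s:.1f} s, "
            f"need at least {required_s:.1f} s"
        )


class EmptyRecordingError(KCIndexError):
    """An operation would leave no samples."""


class NotSynchronizedError(KCIndexError):
    """Operation requires a synchronized, uniformly sampled recording."""


class DegenerateSignalError(KCIndexError):
    """A signal has no variance (dead sensor) or too few samples."""

    def __init__(self, what: str = "signal"):
        self.what = what
        super().__init__(f"degenerate signal: {what}")


class DegenerateCohortError(KCIndexError):
    """A cohort cannot support range normalization (zero spread or too small)."""


class DegenerateLabelsError(KCIndexError):
    """Labeled scores contain only one class (or resampling cannot avoid it)."""


class ConfigError(KCIndexError):
    """Pipeline configuration is invalid."""
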