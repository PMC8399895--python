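"""Exception hierarchy shared across the package."""


class ReachMLError(Exception):
    """Base class for package-specific errors."""


class SchemaError(ReachMLError):
    """A file does not match the expected column schema."""


class DataError(ReachMLError):
    """A file parses but its contents violate a data contract."""


class NoMotionError(ReachMLError):
    """A speed signal contains no detectable motion."""


class EmptyCohortError(ReachMLError):
    """A cohort simulation was requested with zero subjects."""


class ConfigurationError(ReachMLError):
    """A test configuration cannot be satisfied by the supplied dataset."""
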