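"""Exception hierarchy shared across the package."""


class AtcPredError(Exception):
    """Base class for all package errors."""


class ValidationError(AtcPredError, ValueError):
    """Malformed input: bad ATC string, duplicate labels, shape mismatch, bad config."""


class LookupMissingError(AtcPredError, KeyError):
    """An entity (e.g. an ATC code) is absent from a required lookup table."""


class TrainingDivergedError(AtcPredError, RuntimeError):
    """The training loss became non-finite."""
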