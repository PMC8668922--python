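"""Exception hierarchy for ergpred."""


class ErgPredError(Exception):
    """Base class for all ergpred errors."""


class InvalidBandError(ErgPredError):
    """Filter band lies outside the (0, Nyquist) range."""


class AllSweepsRejectedError(ErgPredError):
    """Every sweep exceeded the artifact threshold; averaging is impossible."""


class IncompatibleSweepsError(ErgPredError):
    """Sweeps differ in sample rate, length or stimulus alignment."""


class NoMarkersError(ErgPredError):
    """The trace carries no usable ERG morphology (e.g. flat input)."""


class MissingIWaveError(NoMarkersError):
    """No local maximum after the b-wave; the i-wave cannot be placed."""


class UndefinedRatioError(ErgPredError):
    """PhNR/B ratio requested with a zero b-wave amplitude."""


class EmptyFieldError(ErgPredError):
    """Visual field contains no test locations."""


class DomainError(ErgPredError):
    """An input lies outside the model's physiologic/valid domain."""


class CollinearityError(ErgPredError):
    """Design matrix is rank deficient; OLS coefficients are not identified."""


class InsufficientDataError(ErgPredError):
    """Too few observations to fit the requested model."""


class FoldError(ErgPredError):
    """Cross-validation fold count incompatible with the grouping structure."""


class UndefinedICCError(ErgPredError):
    """Intraclass correlation undefined (no cluster of size >= 2)."""


class BootstrapInstabilityError(ErgPredError):
    """Too many degenerate bootstrap resamples had to be redrawn."""


class ConfigError(ErgPredError):
    """Invalid simulation or run configuration."""
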