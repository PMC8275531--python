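"""Exception hierarchy for the package."""


class MRError(Exception):
    """Base class for all package errors."""


class DataError(MRError):
    """Invalid or inconsistent summary-statistic input."""


class FixtureNotFoundError(MRError, KeyError):
    """Unknown bundled fixture name; message lists the available ones."""


class InsufficientInstrumentsError(MRError):
    """Fewer included instruments than the estimator's minimum."""


class UndefinedRatioError(MRError):
    """Wald ratio requested with a zero exposure effect."""


class DegenerateWeightsError(MRError):
    """All instrument weights are zero."""


class ConfigError(MRError):
    """Invalid analysis configuration (missing columns, bad paths, bad ranges)."""
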