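"""Exception hierarchy shared by all pipeline stages."""


class SSBTaxError(Exception):
    """Base class for all package errors."""


class ConfigurationError(SSBTaxError):
    """A run configuration or parameter block is invalid or incomplete."""


class DomainError(SSBTaxError):
    """An input is outside the physically or epidemiologically valid range."""


class CalibrationError(SSBTaxError):
    """A numerical calibration (market inversion, cohort tuning) failed."""


class DataError(SSBTaxError):
    """Cohort or table data violates an invariant (impossible anthropometry)."""


class SchemaError(SSBTaxError):
    """A CSV or config file does not match the expected schema."""


class EstimationError(SSBTaxError):
    """A survey-weighted estimate cannot be computed (e.g. empty stratum)."""


class PipelineError(SSBTaxError):
    """A pipeline stage failed; message names the stage and scenario."""
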