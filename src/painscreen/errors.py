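"""Exception hierarchy shared across the pipeline.

Two broad classes matter operationally: problems with user-supplied data
(bad tables, empty results after filtering) and problems with the requested
configuration (out-of-range thresholds, impossible simulation settings).
The CLI maps them to exit codes 1 and 2 respectively.
"""


class PainscreenError(Exception):
    """Base class for all package errors."""


class DataError(PainscreenError):
    """Invalid or inconsistent input data (exit code 1 in the CLI)."""


class ConfigError(PainscreenError):
    """Invalid configuration or parameters (exit code 2 in the CLI)."""


class EmptyResultError(DataError):
    """A filter or join left nothing to analyze."""
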