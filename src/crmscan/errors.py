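"""Exception hierarchy shared across the pipeline.

Each class maps to a stable CLI exit code so that shell callers can
distinguish configuration mistakes from malformed data and runtime
failures.
"""


class CrmscanError(Exception):
    """Base class for all pipeline errors."""

    exit_code = 4


class ConfigError(CrmscanError):
    """Invalid configuration (bad key, missing path, inconsistent values)."""

    exit_code = 2


class FormatError(CrmscanError):
    """Malformed input data (FASTA/GFF3/BED/TSV syntax or semantics)."""

    exit_code = 3
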