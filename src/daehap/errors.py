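"""Exception hierarchy shared across the pipeline.

Exit-code mapping in the CLI: DataError/ModelError -> 1, ConfigError and
usage problems -> 2.
"""


class DaehapError(Exception):
    """Base class for all package errors."""


class ConfigError(DaehapError):
    """Invalid configuration value (bad threshold, frequencies not summing to 1 ...)."""


class DataError(DaehapError):
    """Malformed or inconsistent input data (bad ratio, unparseable line ...)."""


class ModelError(DaehapError):
    """A statistical model cannot be fitted on the given data (no events, no variation ...)."""


class UnresolvableHaplotypeError(DataError):
    """The residual allele vector matches no known haplotype pattern."""


class AmbiguousHaplotypeError(DataError):
    """The residual allele vector matches more than one haplotype pattern."""

    def __init__(self, candidates):
        self.candidates = list(candidates)
        super().__init__(
            "residual haplotype matches multiple patterns: "
            + ", ".join(self.candidates)
        )
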