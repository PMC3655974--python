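"""Exception hierarchy shared across the package.

Exit-code mapping used by the command line interface:
``FormatError`` -> 2 (malformed input file), ``ConfigError`` -> 3
(invalid run configuration); everything else -> 1.
"""


class CandidateInteractomeError(Exception):
    """Base class for all package-specific errors."""


class FormatError(CandidateInteractomeError):
    """An input file does not conform to its documented format."""


class ConfigError(CandidateInteractomeError):
    """A run configuration is missing fields or holds invalid values."""


class CurationError(CandidateInteractomeError):
    """Evidence curation cannot produce a valid interactome."""


class MappingError(CandidateInteractomeError):
    """SNP-to-gene mapping or LD pruning received inconsistent inputs."""


class ValidationWarning(UserWarning):
    """Emitted when invalid rows are dropped instead of aborting the read."""
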