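"""Exception hierarchy shared across the package.

Everything user-facing raises a subclass of :class:`OrthoprimerError`
so the CLI can map validation failures to exit code 1 and genuine
internal errors to exit code 2.
"""


class OrthoprimerError(Exception):
    """Base class for all orthoprimer errors."""


class FormatError(OrthoprimerError):
    """Malformed input file (FASTA/FASTQ/TSV/Newick)."""


class AlignmentError(OrthoprimerError):
    """Rows of unequal length, empty alignment, or label problems."""


class IntegrityError(OrthoprimerError):
    """Packaged fixture does not match its checksum manifest."""


class AlphabetError(OrthoprimerError):
    """Sequence contains characters outside the expected alphabet."""


class DegenerateDistributionError(OrthoprimerError):
    """Shuffled-score distribution has zero spread; Z undefined."""


class BudgetError(OrthoprimerError):
    """Primer degeneracy or inosine budget exceeded."""


class WindowError(OrthoprimerError):
    """Primer design window invalid (gap inside it, out of range)."""


class ExpansionError(OrthoprimerError):
    """Degenerate expansion larger than the requested cap."""


class ConfigError(OrthoprimerError):
    """Invalid simulation or pipeline configuration."""


class SizeError(OrthoprimerError):
    """Problem too large for an exhaustive method."""
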