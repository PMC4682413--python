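"""Exception hierarchy.

Everything raised deliberately by this package derives from
:class:`BasecovError`, so callers (and the CLI) can distinguish data problems
from programming errors.
"""


class BasecovError(Exception):
    """Base class for all errors raised by basecov."""


class InputError(BasecovError):
    """A problem with an input file (SAM/FASTA/GTF) that prevents processing."""


class MismatchDescriptorError(InputError):
    """A mismatch-descriptor (MD) string violating the grammar."""


class ReferenceMismatchError(InputError):
    """Alignments reference a chromosome absent from the FASTA reference."""


class TrackOverflowError(BasecovError):
    """A per-position count exceeded the 32-bit track width."""


class InternalConsistencyError(BasecovError):
    """An invariant of the coverage construction was violated (a bug, or
    corrupted intermediate state), e.g. a negative prefix sum."""


class FixturePlanError(BasecovError):
    """A synthetic-fixture specification that cannot be realized."""


class StoreError(BasecovError):
    """Base class for track-store problems."""


class StoreExistsError(StoreError):
    """Refusing to overwrite an already-compiled sample."""


class IncompatibleStoreError(StoreError):
    """Magic/version mismatch when opening a store file."""


class SliceBoundsError(StoreError):
    """Out-of-range (or empty) slice request against a stored track."""


class UnknownTrackError(StoreError):
    """A track name absent from the store catalog at the requested level."""


class QueryError(BasecovError):
    """Base class for query-resolution problems."""


class UnknownChromosomeError(QueryError):
    """Chromosome name not present in the compiled sample."""


class UnknownGeneError(QueryError):
    """Gene name/alias not present in the compiled gene index."""


class GeneIndexMissingError(QueryError):
    """A gene query against a sample compiled without a GTF."""


class UnknownSampleError(QueryError):
    """No compiled store found for the requested sample id."""
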