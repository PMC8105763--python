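"""Exception hierarchy for the vdra package.

Every error raised by the package derives from :class:`VdraError` so callers
can catch the whole family; the subclasses mirror the distinct failure modes
of the pipeline (bad specifications, partition plans, file formats, protocol
misuse, numerical breakdown, and transfer-governance violations).
"""


class VdraError(Exception):
    """Base class for all vdra errors."""


class SpecificationError(VdraError):
    """A cohort or model specification violates its invariants."""


class PlanError(VdraError):
    """A partition or block plan is inconsistent with the data it targets."""


class FormatError(VdraError):
    """A serialized table/partition file is malformed (missing or duplicate
    patient IDs, missing values, non-numeric columns)."""


class AlignmentError(VdraError):
    """Two site partitions do not share the same patient-ID row order."""


class DimensionError(VdraError):
    """A requested mask dimension exceeds the rank bound n - p."""


class DomainError(VdraError):
    """An argument lies outside its mathematical domain (negative weights,
    non-binary outcome for logistic regression)."""


class AssemblyError(VdraError):
    """Gram blocks are dimensionally inconsistent with the column layout."""


class IncompleteBlocksError(AssemblyError):
    """A required Gram block is missing; the message names the (i, j) pair."""


class CollinearityError(VdraError):
    """The global Gram matrix is singular or numerically near-singular."""


class SeparationError(VdraError):
    """Logistic IRLS diverged (complete or quasi-complete separation)."""


class ComparisonError(VdraError):
    """Two regression results are not comparable (model or column order)."""


class ConfigError(VdraError):
    """A network or run configuration is invalid."""


class TrustPermissionError(VdraError):
    """A party other than the analysis center tried to mutate the trust
    matrix."""


class TrustViolationError(VdraError):
    """A transfer forbidden by the trust matrix was attempted; the run is
    terminated."""


class RunTerminatedError(VdraError):
    """A transfer was attempted on an already-terminated run."""


class IntegrityError(VdraError):
    """A delivered file failed its checksum; the manifest is rejected but the
    run continues."""


class RoutingError(VdraError):
    """A transfer references an unknown party."""


class WorkflowError(VdraError):
    """The end-to-end distributed-regression workflow could not complete."""


class ManifestError(VdraError):
    """A transfer manifest is malformed (for example, empty)."""
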