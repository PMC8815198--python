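"""Exception hierarchy for the APOE QC pipeline.

Every failure mode that the pipeline is contractually required to surface
(rather than silently drop) has a dedicated class so callers can branch on it.
"""


class ApoeQCError(Exception):
    """Base class for all package errors."""


class InconsistentHaplotypeError(ApoeQCError):
    """rs429358/rs7412 genotype pair forces a C+T (epsilon-1) haplotype."""


class MissingInputError(ApoeQCError):
    """A required genotype call is missing."""


class LowQualityError(ApoeQCError):
    """Imputation R-squared below the usability floor."""


class DomainError(ApoeQCError):
    """A probability or frequency outside its valid range."""


class InfeasibleLDError(ApoeQCError):
    """Requested D' cannot be realised at the given allele frequencies."""


class EmptyTableError(ApoeQCError):
    """Genotype count table contains no observations."""


class MonomorphicError(ApoeQCError):
    """D' undefined: at least one locus has a fixed allele."""


class NoPairsError(ApoeQCError):
    """No duplicate pairs with overlapping non-missing calls."""


class EmptyStratumError(ApoeQCError):
    """A stratum contains no subjects."""


class NoVariationError(ApoeQCError):
    """Genotype coding is constant; no association model can be fitted."""


class SeparationError(ApoeQCError):
    """Perfect or quasi-perfect separation in the logistic fit.

    Raised instead of returning an unbounded estimate; the message advises
    inspecting the stratum's carrier counts.
    """


class AlleleMismatchError(ApoeQCError):
    """VCF REF/ALT orientation disagrees with the pinned variant definition."""


class MissingVariantError(ApoeQCError):
    """A required variant record is absent from the VCF."""


class HeaderMismatchError(ApoeQCError):
    """TSV header does not match the documented schema."""


class DuplicateSampleIdError(ApoeQCError):
    """The same sample id appears twice in a manifest."""


class MissingSampleError(ApoeQCError):
    """A duplicate pair references a sample id not present in the manifest."""
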