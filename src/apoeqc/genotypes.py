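"""Core domain types: site genotypes, APOE genotypes, and the deterministic
mapping between them.

The APOE epsilon alleles are haplotypes of two missense SNPs:

* rs429358 (T>C): the ALT (C) arm marks epsilon-4;
* rs7412  (C>T): the ALT (T) arm marks epsilon-2;
* the reference arm at both sites is epsilon-3.

A chromosome carrying C at rs429358 *and* T at rs7412 would be the
vanishingly rare epsilon-1 haplotype, which this package assumes absent.
Under that assumption every unphased pair of site genotypes with
ALT429358 + ALT7412 <= 2 maps to exactly one unordered epsilon pair; the
double heterozygote maps to e2/e4 but is flagged ambiguous because the
e1/e3 phasing would fit the same unphased data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Tuple

import numpy as np

from .errors import (
    DomainError,
    InconsistentHaplotypeError,
    LowQualityError,
    MissingInputError,
)

#: Pinned (REF, ALT) alleles for the three variants handled by the pipeline.
#: rs439401 sits ~1.8 kb downstream of APOE; its T allele is the tested allele.
VARIANTS: dict[str, Tuple[str, str]] = {
    "rs429358": ("T", "C"),
    "rs7412": ("C", "T"),
    "rs439401": ("C", "T"),
}

#: Canonical unordered APOE genotype labels, keyed by (#e2, #e4) allele counts.
APOE_LABELS = ("e2/e2", "e2/e3", "e2/e4", "e3/e3", "e3/e4", "e4/e4")

_COUNTS_TO_LABEL = {
    (2, 0): "e2/e2",
    (1, 0): "e2/e3",
    (1, 1): "e2/e4",
    (0, 0): "e3/e3",
    (0, 1): "e3/e4",
    (0, 2): "e4/e4",
}
_LABEL_TO_COUNTS = {v: k for k, v in _COUNTS_TO_LABEL.items()}


class Source(str, Enum):
    """Provenance of an APOE genotype, in no particular priority order."""

    PROVIDED = "PROVIDED"
    IMPUTED = "IMPUTED"
    WGS = "WGS"
    WES_PARTIAL = "WES_PARTIAL"


class VerifyResult(str, Enum):
    """Outcome of checking a provided APOE genotype against a WES rs429358 call."""

    CONFIRMED = "CONFIRMED"
    CONTRADICTED = "CONTRADICTED"
    NON_INFORMATIVE = "NON_INFORMATIVE"


@dataclass(frozen=True)
class SiteGenotype:
    """Unphased diploid call at one of the three pinned SNPs.

    ``alleles`` is an unordered pair of base letters drawn from the variant's
    REF/ALT, or ``None`` for a missing call.
    """

    variant_id: str
    alleles: Optional[Tuple[str, str]]

    def __post_init__(self) -> None:
        if self.variant_id not in VARIANTS:
            raise DomainError(f"unknown variant {self.variant_id!r}")
        if self.alleles is not None:
            ref, alt = VARIANTS[self.variant_id]
            if len(self.alleles) != 2 or any(a not in (ref, alt) for a in self.alleles):
                raise DomainError(
                    f"{self.variant_id}: alleles {self.alleles!r} not in "
                    f"{{{ref}, {alt}}}"
                )
            # canonical order: REF before ALT
            object.__setattr__(
                self, "alleles", tuple(sorted(self.alleles, key=lambda a: a == alt))
            )

    @classmethod
    def from_alt_count(cls, variant_id: str, alt_count: Optional[int]) -> "SiteGenotype":
        if alt_count is None or alt_count < 0:
            return cls(variant_id, None)
        if alt_count not in (0, 1, 2):
            raise DomainError(f"alt count {alt_count} outside 0..2")
        ref, alt = VARIANTS[variant_id]
        return cls(variant_id, tuple([ref] * (2 - alt_count) + [alt] * alt_count))

    @property
    def missing(self) -> bool:
        return self.alleles is None

    @property
    def alt_count(self) -> Optional[int]:
        if self.alleles is None:
            return None
        alt = VARIANTS[self.variant_id][1]
        return sum(a == alt for a in self.alleles)


@dataclass(frozen=True)
class ApoeGenotype:
    """Unordered pair of epsilon alleles with its provenance.

    A ``WES_PARTIAL`` genotype carries only the epsilon-4 arm count
    (``e4_count_only``) because current exome data call rs429358 but not
    rs7412, so e2 cannot be told apart from e3.
    """

    alleles: Optional[Tuple[str, str]]
    source: Source = Source.PROVIDED
    ambiguous: bool = False
    e4_count_only: Optional[int] = field(default=None)

    def __post_init__(self) -> None:
        if self.source is Source.WES_PARTIAL:
            if self.alleles is not None:
                raise DomainError("WES_PARTIAL carries only an e4 count, not a full pair")
            if self.e4_count_only not in (0, 1, 2):
                raise DomainError("WES_PARTIAL requires e4_count_only in {0,1,2}")
        else:
            if self.alleles is None:
                raise DomainError("full APOE genotype requires two alleles")
            pair = tuple(sorted(self.alleles))
            if "/".join(pair) not in APOE_LABELS:
                raise DomainError(f"invalid epsilon pair {self.alleles!r}")
            object.__setattr__(self, "alleles", pair)

    @classmethod
    def from_label(
        cls, label: str, source: Source = Source.PROVIDED, ambiguous: bool = False
    ) -> "ApoeGenotype":
        a, b = sorted(label.strip().lower().split("/"))
        return cls((a, b), source=source, ambiguous=ambiguous)

    @property
    def label(self) -> Optional[str]:
        return None if self.alleles is None else "/".join(self.alleles)

    @property
    def e4_count(self) -> int:
        if self.source is Source.WES_PARTIAL:
            return self.e4_count_only  # type: ignore[return-value]
        return sum(a == "e4" for a in self.alleles)  # type: ignore[union-attr]

    @property
    def e2_count(self) -> int:
        if self.source is Source.WES_PARTIAL:
            raise MissingInputError("WES_PARTIAL cannot count e2 alleles")
        return sum(a == "e2" for a in self.alleles)  # type: ignore[union-attr]


@dataclass(frozen=True)
class DosageRecord:
    """Imputed ALT-allele dosage with its per-variant imputation quality R^2.

    The usability floor for R^2 is 0.8; lower-quality dosages are rejected by
    :func:`hard_call` rather than converted.
    """

    variant_id: str
    dosage: float
    r2: float

    R2_MIN: float = field(default=0.8, repr=False, compare=False)

    def __post_init__(self) -> None:
        if not 0.0 <= self.dosage <= 2.0:
            raise DomainError(f"dosage {self.dosage} outside [0, 2]")
        if not 0.0 <= self.r2 <= 1.0:
            raise DomainError(f"r2 {self.r2} outside [0, 1]")


def apoe_from_snps(
    g429358: SiteGenotype,
    g7412: SiteGenotype,
    source: Source = Source.WGS,
) -> ApoeGenotype:
    """Map unphased rs429358/rs7412 genotypes to the unique epsilon pair.

    Raises
    ------
    MissingInputError
        if either call is missing.
    InconsistentHaplotypeError
        if the ALT counts sum to more than 2, which would force a C+T
        (epsilon-1) haplotype onto one chromosome.
    """
    if g429358.variant_id != "rs429358" or g7412.variant_id != "rs7412":
        raise DomainError("arguments must be rs429358 and rs7412 calls, in that order")
    if g429358.missing or g7412.missing:
        raise MissingInputError("both rs429358 and rs7412 calls are required")
    c4 = g429358.alt_count
    c2 = g7412.alt_count
    if c4 + c2 > 2:
        raise InconsistentHaplotypeError(
            f"rs429358 ALT={c4}, rs7412 ALT={c2}: at least one chromosome must "
            "carry both C and T (epsilon-1), which is assumed absent"
        )
    label = _COUNTS_TO_LABEL[(c2, c4)]
    return ApoeGenotype.from_label(label, source=source, ambiguous=(c4 == 1 and c2 == 1))


def snps_from_apoe(g: ApoeGenotype) -> Tuple[SiteGenotype, SiteGenotype]:
    """Inverse of :func:`apoe_from_snps` (exact for all six epsilon pairs)."""
    if g.source is Source.WES_PARTIAL:
        raise MissingInputError("WES_PARTIAL genotypes do not determine rs7412")
    return (
        SiteGenotype.from_alt_count("rs429358", g.e4_count),
        SiteGenotype.from_alt_count("rs7412", g.e2_count),
    )


def hard_call(
    d: DosageRecord, r2_min: float = 0.8, window: float = 0.4
) -> SiteGenotype:
    """Convert an imputed dosage to a discrete genotype.

    The dosage is rounded to the nearest integer ALT count; calls farther than
    ``window`` from every integer are returned missing rather than guessed.

    Raises
    ------
    LowQualityError
        if ``d.r2`` is below ``r2_min`` — the source is unusable.
    """
    if d.r2 < r2_min:
        raise LowQualityError(
            f"{d.variant_id}: R^2 {d.r2:.3f} below usability floor {r2_min}"
        )
    nearest = int(np.clip(np.rint(d.dosage), 0, 2))
    if abs(d.dosage - nearest) > window:
        return SiteGenotype(d.variant_id, None)
    return SiteGenotype.from_alt_count(d.variant_id, nearest)


def wes_verifies(provided: ApoeGenotype, wes_429358: SiteGenotype) -> VerifyResult:
    """Check a provided APOE genotype against an exome rs429358 call.

    Exome data carry only the epsilon-4 arm, so only provided e3/3, e3/4 and
    e4/4 genotypes are verifiable; any genotype containing e2 is
    NON_INFORMATIVE because e2 and e3 are indistinguishable without rs7412.
    """
    if provided.source is not Source.PROVIDED:
        raise DomainError("verification applies to provided/demographic genotypes")
    if wes_429358.variant_id != "rs429358":
        raise DomainError("WES verification uses the rs429358 call")
    if wes_429358.missing:
        raise MissingInputError("WES rs429358 call is missing")
    if provided.e2_count > 0:
        return VerifyResult.NON_INFORMATIVE
    if provided.e4_count == wes_429358.alt_count:
        return VerifyResult.CONFIRMED
    return VerifyResult.CONTRADICTED


# ---------------------------------------------------------------------------
# Vectorised helpers used by the bulk (DataFrame) code paths.
# ---------------------------------------------------------------------------

# label lookup indexed by 3*c2 + c4; invalid combinations map to "".
_LABEL_LUT = np.array(
    [
        _COUNTS_TO_LABEL.get((c2, c4), "")
        for c2 in range(3)
        for c4 in range(3)
    ],
    dtype=object,
)


def apoe_labels_from_alt_counts(c4: np.ndarray, c2: np.ndarray) -> np.ndarray:
    """Vectorised rs429358/rs7412 ALT counts -> APOE labels.

    Missing (negative) or epsilon-1-implying combinations yield ``""``.
    """
    c4 = np.asarray(c4)
    c2 = np.asarray(c2)
    ok = (c4 >= 0) & (c2 >= 0) & (c4 + c2 <= 2)
    idx = np.where(ok, 3 * c2 + c4, 0)
    out = _LABEL_LUT[idx].copy()
    out[~ok] = ""
    return out


def allele_counts_from_labels(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised APOE labels -> (e2 count, e4 count); missing/"" -> (-1, -1)."""
    labels = np.asarray(labels, dtype=object)
    e2 = np.full(labels.shape, -1, dtype=np.int64)
    e4 = np.full(labels.shape, -1, dtype=np.int64)
    for lab, (c2, c4) in _LABEL_TO_COUNTS.items():
        m = labels == lab
        e2[m] = c2
        e4[m] = c4
    return e2, e4
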