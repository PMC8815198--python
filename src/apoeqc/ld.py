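"""Two-locus haplotype frequency estimation, D/D', and phase-guaranteed strata.

The LD of interest is between an APOE epsilon allele (collapsed to a biallelic
indicator, e.g. "carries e3" per chromosome) and the rs439401 T allele.  Input
is a 3x3 table of unphased genotype counts (rows: indicator-allele count 0/1/2;
columns: T count 0/1/2).  Only the double-heterozygote cell has latent phase;
an EM iteration fractionally assigns it between the coupling (AB/ab) and
repulsion (Ab/aB) resolutions.

Strata construction exploits phase certainty: in e4/4 carriers any rs439401 T
allele necessarily sits on an e4 background, while in e3/4 heterozygotes only
rs439401 homozygotes guarantee a T in phase with e4 — hence the wild-type
versus homozygote (WT vs HOM) design that drops rs439401 heterozygotes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List

import numpy as np
import pandas as pd

from .errors import EmptyTableError, MonomorphicError
from .genotypes import allele_counts_from_labels

#: Stratum labels for the association designs.
E44_ADDITIVE = "E44_ADDITIVE"
E34_WT_VS_HOM = "E34_WT_VS_HOM"
E34_ADDITIVE = "E34_ADDITIVE"
E33_ADDITIVE = "E33_ADDITIVE"
FULL_ADJUSTED = "FULL_ADJUSTED"

STRATA = (E44_ADDITIVE, E34_WT_VS_HOM, E34_ADDITIVE, E33_ADDITIVE, FULL_ADJUSTED)


@dataclass
class HaplotypeFreqs:
    """EM-estimated two-locus haplotype frequencies.

    A is the collapsed epsilon-allele indicator, B the rs439401 T allele.
    ``loglik_path`` records the log-likelihood after each EM iteration
    (non-decreasing by construction of EM).
    """

    p_AB: float
    p_Ab: float
    p_aB: float
    p_ab: float
    loglik: float
    n_iter: int
    n: int
    loglik_path: List[float] = field(default_factory=list, repr=False)

    @property
    def p_A(self) -> float:
        return self.p_AB + self.p_Ab

    @property
    def p_B(self) -> float:
        return self.p_AB + self.p_aB

    def as_array(self) -> np.ndarray:
        return np.array([self.p_AB, self.p_Ab, self.p_aB, self.p_ab])


def genotype_table(a_counts: np.ndarray, b_counts: np.ndarray) -> np.ndarray:
    """3x3 genotype count table from per-subject allele counts (missing < 0)."""
    a = np.asarray(a_counts)
    b = np.asarray(b_counts)
    ok = (a >= 0) & (b >= 0)
    table = np.zeros((3, 3), dtype=np.int64)
    np.add.at(table, (a[ok], b[ok]), 1)
    return table


def _cell_probs(f: np.ndarray) -> np.ndarray:
    """Genotype cell probabilities (3x3) from haplotype freqs [AB, Ab, aB, ab]."""
    fAB, fAb, faB, fab = f
    p = np.empty((3, 3))
    p[0, 0] = fab * fab
    p[0, 1] = 2 * faB * fab
    p[0, 2] = faB * faB
    p[1, 0] = 2 * fAb * fab
    p[1, 1] = 2 * fAB * fab + 2 * fAb * faB
    p[1, 2] = 2 * fAB * faB
    p[2, 0] = fAb * fAb
    p[2, 1] = 2 * fAB * fAb
    p[2, 2] = fAB * fAB
    return p


def loglik_table(counts: np.ndarray, f: np.ndarray) -> float:
    """Multinomial log-likelihood of a 3x3 table under haplotype freqs ``f``."""
    p = _cell_probs(np.asarray(f, dtype=float))
    c = np.asarray(counts, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(c > 0, c * np.log(p), 0.0)
    return float(terms.sum())


def em_haplotype_freqs(
    counts: np.ndarray, tol: float = 1e-8, max_iter: int = 1000
) -> HaplotypeFreqs:
    """EM over the 3x3 unphased genotype table.

    Starts at linkage equilibrium; converges when the largest haplotype
    frequency change drops below ``tol`` or after ``max_iter`` iterations.
    Only the (1, 1) double-heterozygote cell carries latent phase.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.shape != (3, 3):
        raise EmptyTableError("expected a 3x3 genotype count table")
    n = counts.sum()
    if n < 1:
        raise EmptyTableError("genotype table is empty")

    # Allele frequencies are fully determined by the table margins.
    a_counts = counts.sum(axis=1)
    b_counts = counts.sum(axis=0)
    p_A = (a_counts @ np.arange(3)) / (2 * n)
    p_B = (b_counts @ np.arange(3)) / (2 * n)

    # Phase-known haplotype contributions (everything except cell (1,1)).
    fixed = np.zeros(4)  # AB, Ab, aB, ab
    fixed[0] = 2 * counts[2, 2] + counts[2, 1] + counts[1, 2]
    fixed[1] = 2 * counts[2, 0] + counts[2, 1] + counts[1, 0]
    fixed[2] = 2 * counts[0, 2] + counts[0, 1] + counts[1, 2]
    fixed[3] = 2 * counts[0, 0] + counts[0, 1] + counts[1, 0]
    n_dh = counts[1, 1]

    f = np.array(
        [p_A * p_B, p_A * (1 - p_B), (1 - p_A) * p_B, (1 - p_A) * (1 - p_B)]
    )
    f = np.clip(f, 1e-12, None)
    f /= f.sum()

    path: List[float] = []
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        # E-step: split the double heterozygotes between phase resolutions.
        coupling = f[0] * f[3]
        repulsion = f[1] * f[2]
        denom = coupling + repulsion
        w = 0.5 if denom == 0 else coupling / denom
        hap = fixed.copy()
        hap[0] += n_dh * w
        hap[3] += n_dh * w
        hap[1] += n_dh * (1 - w)
        hap[2] += n_dh * (1 - w)
        new_f = hap / (2 * n)
        delta = np.max(np.abs(new_f - f))
        f = new_f
        path.append(loglik_table(counts, f))
        if delta < tol:
            break

    return HaplotypeFreqs(
        p_AB=float(f[0]),
        p_Ab=float(f[1]),
        p_aB=float(f[2]),
        p_ab=float(f[3]),
        loglik=path[-1],
        n_iter=n_iter,
        n=int(n),
        loglik_path=path,
    )


def d_coefficient(h: HaplotypeFreqs) -> float:
    """Raw LD coefficient D = p_AB - p_A * p_B."""
    return h.p_AB - h.p_A * h.p_B


def dprime(h: HaplotypeFreqs) -> float:
    """Normalised LD: D' = D / D_max, in [-1, 1].

    D_max is min(p_A(1-p_B), (1-p_A)p_B) when D > 0 and
    min(p_A p_B, (1-p_A)(1-p_B)) when D < 0; D = 0 returns 0.
    """
    p_A, p_B = h.p_A, h.p_B
    if min(p_A, 1 - p_A) <= 0 or min(p_B, 1 - p_B) <= 0:
        raise MonomorphicError("D' undefined: a locus is monomorphic")
    d = d_coefficient(h)
    if d == 0:
        return 0.0
    if d > 0:
        d_max = min(p_A * (1 - p_B), (1 - p_A) * p_B)
    else:
        d_max = min(p_A * p_B, (1 - p_A) * (1 - p_B))
    return float(d / d_max)


def ld_for_allele(
    apoe_labels: np.ndarray, t_counts: np.ndarray, allele: str = "e3"
) -> HaplotypeFreqs:
    """EM haplotype frequencies between one epsilon allele and rs439401-T.

    ``allele`` selects which epsilon allele is collapsed to the biallelic A
    indicator (that allele versus the other two pooled).
    """
    e2, e4 = allele_counts_from_labels(np.asarray(apoe_labels, dtype=object))
    valid = e2 >= 0
    if allele == "e2":
        a = e2
    elif allele == "e4":
        a = e4
    elif allele == "e3":
        a = 2 - e2 - e4
    else:
        raise ValueError(f"allele must be e2, e3, or e4, not {allele!r}")
    a = np.where(valid, a, -1)
    return em_haplotype_freqs(genotype_table(a, np.asarray(t_counts)))


def assign_strata(subjects: pd.DataFrame) -> Dict[str, pd.DataFrame]:
    """Build the five association designs from adjudicated subjects.

    Expects columns ``apoe`` (label) and ``rs439401`` (T-allele count, -1 for
    missing).  Each returned frame carries a genotype coding column ``g``:

    * E44_ADDITIVE: e4/4 carriers, g = T count (any T is in phase with e4);
    * E34_WT_VS_HOM: e3/4 carriers, C/C -> g=0 and T/T -> g=1; rs439401
      heterozygotes are dropped because their single T may sit on either
      background;
    * E34_ADDITIVE, E33_ADDITIVE: additive T count within the stratum;
    * FULL_ADJUSTED: all genotypes, additive T count, with e2/e4 allele
      dosages added as covariate columns.

    e2/4 carriers enter no genotype stratum (sample paucity) but do remain in
    the full-sample design.
    """
    df = subjects.loc[subjects["rs439401"] >= 0].copy()
    out: Dict[str, pd.DataFrame] = {}

    e44 = df.loc[df["apoe"] == "e4/e4"].copy()
    e44["g"] = e44["rs439401"].astype(float)
    out[E44_ADDITIVE] = e44

    e34 = df.loc[df["apoe"] == "e3/e4"].copy()
    wt_hom = e34.loc[e34["rs439401"].isin([0, 2])].copy()
    wt_hom["g"] = (wt_hom["rs439401"] // 2).astype(float)
    out[E34_WT_VS_HOM] = wt_hom

    e34_add = e34.copy()
    e34_add["g"] = e34_add["rs439401"].astype(float)
    out[E34_ADDITIVE] = e34_add

    e33 = df.loc[df["apoe"] == "e3/e3"].copy()
    e33["g"] = e33["rs439401"].astype(float)
    out[E33_ADDITIVE] = e33

    full = df.copy()
    e2, e4 = allele_counts_from_labels(full["apoe"].to_numpy(dtype=object))
    full["g"] = full["rs439401"].astype(float)
    full["e2_dosage"] = e2.astype(float)
    full["e4_dosage"] = e4.astype(float)
    out[FULL_ADJUSTED] = full
    return out
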