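"""Synthetic multi-cohort case-control generator with known ground truth.

Each subject receives two APOE-region haplotypes drawn from a six-class
distribution (epsilon allele x rs439401 allele) constructed to hit a target
D' between rs439401-T and epsilon-3 plus a small mass of the rare e4-T
("in-phase") haplotype.  Disease status follows a logistic model with the
canonical APOE risk profile: roughly 3-fold risk per e4 copy, ~12-fold for
e4/4, and ~0.5-fold per e2 copy.

Observed data are then emitted per cohort with a configurable source profile:

* ``array``  — provided APOE + imputed rs429358/rs7412 dosages (R^2 >= 0.8)
  + a direct rs439401 array call (arrays never type rs429358 directly);
* ``wgs``    — provided APOE + WGS calls at all three sites;
* ``wes``    — provided APOE + a WES call at rs429358 only.

Every source has its own error process, and one cohort is conventionally
configured with an elevated provided-APOE error rate (the "bad cohort"),
which is what the downstream adjudication and concordance diagnostics are
designed to catch.  Duplicated subjects are re-emitted under independent
error draws so duplicate-concordance checks have something to measure.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .errors import DomainError, InfeasibleLDError
from .genotypes import APOE_LABELS

PROFILES = ("array", "wgs", "wes")

_LABEL_ARR = np.array(APOE_LABELS, dtype=object)
_LABEL_INDEX = {lab: i for i, lab in enumerate(APOE_LABELS)}


@dataclass(frozen=True)
class CohortSpec:
    """One cohort: size, source profile, and its provided-APOE error rate."""

    name: str
    n: int
    source_profile: str = "array"
    provided_error_rate: float = 0.005

    def __post_init__(self) -> None:
        if self.source_profile not in PROFILES:
            raise DomainError(f"unknown source profile {self.source_profile!r}")
        if not 0.0 <= self.provided_error_rate <= 1.0:
            raise DomainError("provided_error_rate outside [0, 1]")


@dataclass(frozen=True)
class SimConfig:
    """Full generator configuration; all randomness flows from ``seed``."""

    seed: int
    cohorts: Tuple[CohortSpec, ...]
    apoe_allele_freqs: Tuple[float, float, float] = (0.08, 0.77, 0.15)  # e2, e3, e4
    rs439401_t_freq: float = 0.36
    target_dprime: float = 0.95  # e3 vs rs439401-T
    rare_inphase_freq: float = 0.002  # e4-T haplotype frequency
    or_per_e4: float = 3.0
    or_e4e4: float = 12.0
    or_per_e2: float = 0.5
    base_prevalence: float = 0.5
    age_mean_sd: Tuple[float, float] = (74.0, 8.0)
    dup_rate: float = 0.03
    imputation_error_rate: float = 0.002
    wgs_error_rate: float = 0.0005
    provided_missing_rate: float = 0.03
    rs439401_missing_rate: float = 0.05

    def __post_init__(self) -> None:
        f = self.apoe_allele_freqs
        if abs(sum(f) - 1.0) > 1e-9 or any(x < 0 for x in f):
            raise DomainError("apoe_allele_freqs must be a simplex")
        for name in (
            "rs439401_t_freq",
            "target_dprime",
            "rare_inphase_freq",
            "base_prevalence",
            "dup_rate",
            "imputation_error_rate",
            "wgs_error_rate",
            "provided_missing_rate",
            "rs439401_missing_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise DomainError(f"{name} {v} outside [0, 1]")
        for name in ("or_per_e4", "or_e4e4", "or_per_e2"):
            if getattr(self, name) <= 0:
                raise DomainError(f"{name} must be positive")


def default_config(seed: int, n_total: int = 20_000) -> SimConfig:
    """The standard study conditions: five cohorts of mixed source types,
    one array cohort ("COH_A") with an elevated (5%) provided-APOE error rate
    at the top of the plausible direct-genotyping error range, the others at
    0.5%."""
    fracs = (0.30, 0.25, 0.20, 0.15, 0.10)
    profiles = ("array", "array", "array", "wgs", "wes")
    errors = (0.05, 0.005, 0.005, 0.005, 0.005)
    names = ("COH_A", "COH_B", "COH_C", "COH_D", "COH_E")
    cohorts = tuple(
        CohortSpec(nm, max(1, int(round(fr * n_total))), pr, er)
        for nm, fr, pr, er in zip(names, fracs, profiles, errors)
    )
    return SimConfig(seed=seed, cohorts=cohorts)


# ---------------------------------------------------------------------------
# Haplotype distribution
# ---------------------------------------------------------------------------

def haplotype_distribution(cfg: SimConfig) -> pd.DataFrame:
    """Six-class haplotype frequencies (epsilon allele x rs439401 allele).

    The e3-T haplotype frequency is set so that D' between the e3 indicator
    and T equals ``target_dprime``; the e4-T haplotype gets
    ``rare_inphase_freq``; the remaining T mass goes to e2-T.

    Raises InfeasibleLDError when the requested D' / rare-haplotype mass
    cannot be realised at the configured allele frequencies.
    """
    f2, f3, f4 = cfg.apoe_allele_freqs
    pt = cfg.rs439401_t_freq
    d_max = min(f3 * (1 - pt), (1 - f3) * pt)
    h3T = f3 * pt + cfg.target_dprime * d_max
    h4T = cfg.rare_inphase_freq
    h2T = pt - h3T - h4T
    rows = {
        ("e2", 1): h2T,
        ("e3", 1): h3T,
        ("e4", 1): h4T,
        ("e2", 0): f2 - h2T,
        ("e3", 0): f3 - h3T,
        ("e4", 0): f4 - h4T,
    }
    if any(v < -1e-12 for v in rows.values()):
        raise InfeasibleLDError(
            "target D' / rare in-phase frequency infeasible at these allele "
            f"frequencies: {rows}"
        )
    df = pd.DataFrame(
        [(a, t, max(0.0, f)) for (a, t), f in rows.items()],
        columns=["allele", "t", "freq"],
    )
    df["freq"] = df["freq"] / df["freq"].sum()
    return df


# ---------------------------------------------------------------------------
# Truth table
# ---------------------------------------------------------------------------

def simulate_haplotypes(cfg: SimConfig) -> pd.DataFrame:
    """Draw the ground-truth table: haplotypes, genotype, phenotype, covariates.

    One row per subject; duplicates are a property of emission, not of truth.
    """
    rng = np.random.default_rng(cfg.seed)
    haps = haplotype_distribution(cfg)
    n = sum(c.n for c in cfg.cohorts)

    hap_idx1 = rng.choice(len(haps), size=n, p=haps["freq"].to_numpy())
    hap_idx2 = rng.choice(len(haps), size=n, p=haps["freq"].to_numpy())
    allele = haps["allele"].to_numpy(dtype=object)
    tarm = haps["t"].to_numpy()

    a1, a2 = allele[hap_idx1], allele[hap_idx2]
    t1, t2 = tarm[hap_idx1], tarm[hap_idx2]
    e2 = (a1 == "e2").astype(int) + (a2 == "e2").astype(int)
    e4 = (a1 == "e4").astype(int) + (a2 == "e4").astype(int)
    # LUT over 3*e2 + e4; e2 + e4 <= 2 always holds for true genotypes
    lut = np.array(
        ["e3/e3", "e3/e4", "e4/e4", "e2/e3", "e2/e4", "", "e2/e2", "", ""],
        dtype=object,
    )
    apoe = lut[3 * e2 + e4]

    # Logistic disease model; intercept solved so the emitted sample has the
    # configured case fraction (case-control design, not population prevalence).
    lp = (
        np.log(cfg.or_per_e4) * e4
        + (np.log(cfg.or_e4e4) - 2 * np.log(cfg.or_per_e4)) * (e4 == 2)
        + np.log(cfg.or_per_e2) * e2
    )

    def mean_prob(alpha: float) -> float:
        return float(np.mean(1.0 / (1.0 + np.exp(-(alpha + lp))))) - cfg.base_prevalence

    alpha = brentq(mean_prob, -30.0, 30.0)
    dx = np.where(
        rng.random(n) < 1.0 / (1.0 + np.exp(-(alpha + lp))), "AD", "CN"
    )

    mu, sd = cfg.age_mean_sd
    # ages truncated at 40: resample the left tail
    age = rng.normal(mu, sd, size=n)
    low = age < 40
    while low.any():
        age[low] = rng.normal(mu, sd, size=int(low.sum()))
        low = age < 40

    cohort = np.repeat(
        np.array([c.name for c in cfg.cohorts], dtype=object),
        [c.n for c in cfg.cohorts],
    )
    pcs = rng.normal(size=(n, 5))

    truth = pd.DataFrame(
        {
            "subject_id": np.char.add(
                "SUBJ", np.char.zfill(np.arange(n).astype(str), 7)
            ).astype(object),
            "cohort": cohort,
            "dx": dx,
            "age": np.round(age, 1),
            "sex": np.where(rng.random(n) < 0.55, "F", "M"),
            "hap1_apoe": a1,
            "hap2_apoe": a2,
            "hap1_t": t1.astype(int),
            "hap2_t": t2.astype(int),
            "apoe_true": apoe,
            "rs439401_true": (t1 + t2).astype(int),
            "e2_true": e2,
            "e4_true": e4,
        }
    )
    for k in range(5):
        truth[f"PC{k+1}"] = np.round(pcs[:, k], 4)
    return truth


# ---------------------------------------------------------------------------
# Observed-source emission
# ---------------------------------------------------------------------------

@dataclass
class Dataset:
    """In-memory bundle of everything the generator emits."""

    manifest: pd.DataFrame
    vcf_calls: pd.DataFrame  # sample_id + alt counts per variant (-1 missing)
    dosages: pd.DataFrame  # long: sample_id, variant, dosage, r2
    dup_pairs: pd.DataFrame  # sample_id_a, sample_id_b
    truth: pd.DataFrame
    config: SimConfig


def _wrong_label_idx(idx: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Uniform draw from the five non-true APOE labels (symmetric kernel)."""
    return (idx + 1 + rng.integers(0, 5, size=idx.shape)) % 6


def _perturb_alt(c: np.ndarray, err: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Replace erroneous calls with a uniform draw from the other two counts."""
    wrong = (c + 1 + rng.integers(0, 2, size=c.shape)) % 3
    return np.where(err, wrong, c)


def emit_observed_sources(truth: pd.DataFrame, cfg: SimConfig) -> Dataset:
    """Emit per-sample observations for every subject plus duplicate samples.

    Error processes per source: provided APOE flips to a uniformly chosen
    wrong genotype at the cohort's rate; imputed dosages are built from the
    true site genotypes after an independent per-variant error, with dosage
    noise small enough that the hard call recovers the (possibly erroneous)
    genotype and R^2 drawn uniformly on [0.8, 1]; WGS/WES site calls err at
    ``wgs_error_rate`` per variant, as does the array rs439401 call.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1_000_003]))
    cohort_by_name = {c.name: c for c in cfg.cohorts}

    n = len(truth)
    # duplicate samples: each flagged subject gets one extra sample in a
    # random cohort (possibly its own) with that cohort's profile and errors.
    is_dup = rng.random(n) < cfg.dup_rate
    cohort_names = np.array([c.name for c in cfg.cohorts], dtype=object)
    dup_cohort = rng.choice(cohort_names, size=int(is_dup.sum()))

    rows = [
        pd.DataFrame(
            {
                "sample_id": truth["subject_id"] + "_s0",
                "subject_id": truth["subject_id"],
                "cohort": truth["cohort"],
                "replicate": 0,
            }
        ),
        pd.DataFrame(
            {
                "sample_id": truth.loc[is_dup, "subject_id"] + "_s1",
                "subject_id": truth.loc[is_dup, "subject_id"],
                "cohort": dup_cohort,
                "replicate": 1,
            }
        ),
    ]
    samples = pd.concat(rows, ignore_index=True)
    samples = samples.merge(
        truth[
            ["subject_id", "dx", "age", "sex", "apoe_true", "rs439401_true",
             "e2_true", "e4_true"] + [f"PC{k+1}" for k in range(5)]
        ],
        on="subject_id",
        how="left",
    )
    m = len(samples)
    profile = samples["cohort"].map(
        {c.name: c.source_profile for c in cfg.cohorts}
    ).to_numpy(dtype=object)
    perr = samples["cohort"].map(
        {c.name: c.provided_error_rate for c in cfg.cohorts}
    ).to_numpy()

    true_idx = np.array(
        [_LABEL_INDEX[l] for l in samples["apoe_true"]], dtype=np.int64
    )
    c4_true = samples["e4_true"].to_numpy()
    c2_true = samples["e2_true"].to_numpy()
    t_true = samples["rs439401_true"].to_numpy()

    # provided APOE
    prov_idx = np.where(
        rng.random(m) < perr, _wrong_label_idx(true_idx, rng), true_idx
    )
    provided = _LABEL_ARR[prov_idx].copy()
    provided[rng.random(m) < cfg.provided_missing_rate] = ""

    # sequencing calls (WGS: all three sites; WES: rs429358 only)
    c4_seq = _perturb_alt(c4_true, rng.random(m) < cfg.wgs_error_rate, rng)
    c2_seq = _perturb_alt(c2_true, rng.random(m) < cfg.wgs_error_rate, rng)
    t_seq = _perturb_alt(t_true, rng.random(m) < cfg.wgs_error_rate, rng)
    t_array = _perturb_alt(t_true, rng.random(m) < cfg.wgs_error_rate, rng)

    is_array = profile == "array"
    is_wgs = profile == "wgs"
    is_wes = profile == "wes"

    vcf = pd.DataFrame({"sample_id": samples["sample_id"]})
    vcf["rs429358"] = np.where(is_wgs | is_wes, c4_seq, -1)
    vcf["rs7412"] = np.where(is_wgs, c2_seq, -1)
    t_obs = np.where(is_wgs, t_seq, np.where(is_array, t_array, -1))
    t_obs = np.where(
        (t_obs >= 0) & (rng.random(m) < cfg.rs439401_missing_rate), -1, t_obs
    )
    vcf["rs439401"] = t_obs

    # imputed dosages for array samples
    dos_frames = []
    for variant, c_true in (("rs429358", c4_true), ("rs7412", c2_true)):
        c_imp = _perturb_alt(
            c_true, rng.random(m) < cfg.imputation_error_rate, rng
        )
        dosage = np.clip(
            c_imp + rng.uniform(-0.15, 0.15, size=m), 0.0, 2.0
        )
        r2 = rng.uniform(0.8, 1.0, size=m)
        dos_frames.append(
            pd.DataFrame(
                {
                    "sample_id": samples.loc[is_array, "sample_id"],
                    "variant": variant,
                    "dosage": np.round(dosage[is_array], 4),
                    "r2": np.round(r2[is_array], 4),
                }
            )
        )
    dosages = pd.concat(dos_frames, ignore_index=True)

    flags = np.where(is_array, "provided,array", np.where(is_wgs, "provided,wgs", "provided,wes"))
    manifest = pd.DataFrame(
        {
            "sample_id": samples["sample_id"],
            "subject_id": samples["subject_id"],
            "cohort": samples["cohort"],
            "dx": samples["dx"],
            "age": samples["age"],
            "sex": samples["sex"],
        }
    )
    for k in range(5):
        manifest[f"PC{k+1}"] = samples[f"PC{k+1}"]
    manifest["provided_apoe"] = provided
    manifest["source_flags"] = flags

    dup_pairs = pd.DataFrame(
        {
            "sample_id_a": truth.loc[is_dup, "subject_id"] + "_s0",
            "sample_id_b": truth.loc[is_dup, "subject_id"] + "_s1",
        }
    ).reset_index(drop=True)

    return Dataset(
        manifest=manifest,
        vcf_calls=vcf,
        dosages=dosages,
        dup_pairs=dup_pairs,
        truth=truth,
        config=cfg,
    )


def simulate_dataset(cfg: SimConfig) -> Dataset:
    """Convenience: truth + emission in one call."""
    return emit_observed_sources(simulate_haplotypes(cfg), cfg)
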