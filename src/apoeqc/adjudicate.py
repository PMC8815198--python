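"""Duplicate harmonization and two-stage APOE genotype adjudication.

Approach 1 (conventional): one prioritized APOE genotype per subject, taking
WGS over a WES-verified provided genotype over a bare provided genotype;
imputation is entirely ignored. Provided-only duplicate groups with
discordant provided APOE are excluded, as are groups whose WGS and WES calls
contradict each other.

Approach 2 (stringent) extends approach 1: subjects whose prioritized
genotype came from a provided/demographic source but disagrees with their
high-quality imputed genotype (both component variants at R^2 >= 0.8 with
non-missing hard calls) are additionally excluded. Sequencing-sourced
genotypes are immune. An optional check against later-released sequencing
data excludes subjects it contradicts.

Every exclusion is recorded with a reason; nothing is dropped silently.
"""

from __future__ import annotations

from typing import Tuple

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from .errors import MissingSampleError
from .genotypes import allele_counts_from_labels

# Exclusion reasons, in the order they are applied along the pipeline.
NONE = ""
DUP_DISCORDANT_PROVIDED = "DUP_DISCORDANT_PROVIDED"
WGS_WES_DISCORDANT = "WGS_WES_DISCORDANT"
WES_CONTRADICTED = "WES_CONTRADICTED"
NO_APOE = "NO_APOE"
NEW_SEQ_DISCORDANT = "NEW_SEQ_DISCORDANT"
APPROACH2_IMPUTED_DISCORDANT = "APPROACH2_IMPUTED_DISCORDANT"
AGE_FILTER = "AGE_FILTER"
DX_FILTER = "DX_FILTER"

EXCLUSION_REASONS = (
    DUP_DISCORDANT_PROVIDED,
    WGS_WES_DISCORDANT,
    WES_CONTRADICTED,
    NO_APOE,
    NEW_SEQ_DISCORDANT,
    APPROACH2_IMPUTED_DISCORDANT,
    AGE_FILTER,
    DX_FILTER,
)

_COVARIATE_COLS = ["cohort", "dx", "age", "sex"] + [f"PC{k+1}" for k in range(5)]


# ---------------------------------------------------------------------------
# Sample-level source derivation
# ---------------------------------------------------------------------------

def build_sample_table(
    manifest: pd.DataFrame,
    vcf_calls: pd.DataFrame,
    dosages: pd.DataFrame,
    r2_min: float = 0.8,
    hard_call_window: float = 0.4,
) -> pd.DataFrame:
    """Derive per-sample APOE source genotypes from the raw inputs.

    Adds: ``provided`` (label or ""), ``wgs_apoe`` (label from WGS
    rs429358+rs7412, "" when unavailable), ``wgs_inconsistent`` (True when the
    WGS site pair implies an epsilon-1 haplotype — surfaced, and the call is
    not used), ``wes_c4`` (WES rs429358 ALT count, -1 when absent),
    ``imputed`` (hard-called label, "" when either variant fails the R^2
    floor or the hard-call window), ``imputed_ambiguous``, and ``rs439401``
    (ALT count, -1 missing).
    """
    df = manifest.merge(vcf_calls, on="sample_id", how="left")
    for v in ("rs429358", "rs7412", "rs439401"):
        if v not in df.columns:
            df[v] = -1
        df[v] = df[v].fillna(-1).astype(np.int64)

    flags = df["source_flags"].fillna("").astype(str)
    has_wgs = flags.str.contains("wgs").to_numpy()
    has_wes = flags.str.contains("wes").to_numpy()

    df["provided"] = df["provided_apoe"].fillna("").astype(str)

    c4 = df["rs429358"].to_numpy()
    c2 = df["rs7412"].to_numpy()
    wgs_ok = has_wgs & (c4 >= 0) & (c2 >= 0)
    inconsistent = wgs_ok & (c4 + c2 > 2)
    lut = {
        (2, 0): "e4/e4", (1, 0): "e3/e4", (0, 0): "e3/e3",
        (0, 1): "e2/e3", (1, 1): "e2/e4", (0, 2): "e2/e2",
    }
    wgs_apoe = np.full(len(df), "", dtype=object)
    usable = wgs_ok & ~inconsistent
    wgs_apoe[usable] = [lut[(a, b)] for a, b in zip(c4[usable], c2[usable])]
    df["wgs_apoe"] = wgs_apoe
    df["wgs_inconsistent"] = inconsistent
    df["wes_c4"] = np.where(has_wes & (c4 >= 0), c4, -1)

    imputed, ambiguous = _hard_call_imputed(df, dosages, r2_min, hard_call_window)
    df["imputed"] = imputed
    df["imputed_ambiguous"] = ambiguous
    return df


def _hard_call_imputed(
    df: pd.DataFrame, dosages: pd.DataFrame, r2_min: float, window: float
) -> Tuple[np.ndarray, np.ndarray]:
    n = len(df)
    imputed = np.full(n, "", dtype=object)
    ambiguous = np.zeros(n, dtype=bool)
    if dosages is None or len(dosages) == 0:
        return imputed, ambiguous
    wide = dosages.pivot_table(
        index="sample_id", columns="variant", values=["dosage", "r2"], aggfunc="first"
    )
    calls = {}
    for variant in ("rs429358", "rs7412"):
        if ("dosage", variant) not in wide.columns:
            return imputed, ambiguous
        d = wide[("dosage", variant)].to_numpy(dtype=float)
        r2 = wide[("r2", variant)].to_numpy(dtype=float)
        nearest = np.clip(np.rint(d), 0, 2)
        ok = (r2 >= r2_min) & (np.abs(d - nearest) <= window) & ~np.isnan(d)
        calls[variant] = np.where(ok, nearest, -1).astype(np.int64)
    c4 = pd.Series(calls["rs429358"], index=wide.index)
    c2 = pd.Series(calls["rs7412"], index=wide.index)
    c4 = df["sample_id"].map(c4).fillna(-1).astype(np.int64).to_numpy()
    c2 = df["sample_id"].map(c2).fillna(-1).astype(np.int64).to_numpy()
    valid = (c4 >= 0) & (c2 >= 0) & (c4 + c2 <= 2)
    lut = {
        (2, 0): "e4/e4", (1, 0): "e3/e4", (0, 0): "e3/e3",
        (0, 1): "e2/e3", (1, 1): "e2/e4", (0, 2): "e2/e2",
    }
    imputed[valid] = [lut[(a, b)] for a, b in zip(c4[valid], c2[valid])]
    ambiguous[:] = valid & (c4 == 1) & (c2 == 1)
    return imputed, ambiguous


# ---------------------------------------------------------------------------
# Duplicate harmonization
# ---------------------------------------------------------------------------

def harmonize_duplicates(
    samples: pd.DataFrame, dup_pairs: pd.DataFrame
) -> pd.DataFrame:
    """Collapse duplicate samples into one record per subject.

    Duplicate pairs are closed transitively (connected components); samples in
    no pair form singleton groups. Provided-only groups with discordant
    provided APOE are flagged DUP_DISCORDANT_PROVIDED; groups whose WGS and
    WES (or WGS and WGS) calls contradict each other are flagged
    WGS_WES_DISCORDANT.
    """
    ids = samples["sample_id"].to_numpy(dtype=object)
    idx = {s: i for i, s in enumerate(ids)}
    n = len(ids)
    if len(dup_pairs):
        for col in ("sample_id_a", "sample_id_b"):
            unknown = set(dup_pairs[col]) - idx.keys()
            if unknown:
                raise MissingSampleError(
                    f"duplicate pairs reference unknown samples: {sorted(unknown)[:5]}"
                )
        ia = dup_pairs["sample_id_a"].map(idx).to_numpy()
        ib = dup_pairs["sample_id_b"].map(idx).to_numpy()
        adj = coo_matrix(
            (np.ones(len(ia)), (ia, ib)), shape=(n, n)
        )
        _, labels = connected_components(adj, directed=False)
    else:
        labels = np.arange(n)

    df = samples.reset_index(drop=True)
    df = df.sort_values("sample_id", kind="stable")
    df = df.assign(dup_group=labels[df.index.to_numpy()]).reset_index(drop=True)

    gb = df.groupby("dup_group", sort=True)
    out = gb[["subject_id"] + _COVARIATE_COLS].first()
    out["n_samples"] = gb.size()

    # Distinct non-missing values per source: 0 -> absent, 1 -> usable,
    # >1 -> within-group discordance.
    prov = df["provided"].mask(df["provided"] == "")
    wgs = df["wgs_apoe"].mask(df["wgs_apoe"] == "")
    imp = df["imputed"].mask(df["imputed"] == "")
    wes = df["wes_c4"].where(df["wes_c4"] >= 0)
    t = df["rs439401"].where(df["rs439401"] >= 0)
    agg = pd.DataFrame(
        {
            "prov_nu": prov.groupby(df["dup_group"]).nunique(),
            "prov_first": prov.groupby(df["dup_group"]).first(),
            "wgs_nu": wgs.groupby(df["dup_group"]).nunique(),
            "wgs_first": wgs.groupby(df["dup_group"]).first(),
            "imp_nu": imp.groupby(df["dup_group"]).nunique(),
            "imp_first": imp.groupby(df["dup_group"]).first(),
            "wes_nu": wes.groupby(df["dup_group"]).nunique(),
            "wes_first": wes.groupby(df["dup_group"]).first(),
            "t_nu": t.groupby(df["dup_group"]).nunique(),
            "t_first": t.groupby(df["dup_group"]).first(),
        }
    )

    out["provided"] = np.where(agg["prov_nu"] == 1, agg["prov_first"].fillna(""), "")
    out["wgs_apoe"] = np.where(agg["wgs_nu"] == 1, agg["wgs_first"].fillna(""), "")
    out["wgs_inconsistent"] = gb["wgs_inconsistent"].any()
    out["wes_c4"] = np.where(agg["wes_nu"] == 1, agg["wes_first"].fillna(-1), -1).astype(
        np.int64
    )
    out["imputed"] = np.where(agg["imp_nu"] == 1, agg["imp_first"].fillna(""), "")
    amb = (df["imputed"] != "") & df["imputed_ambiguous"]
    out["imputed_ambiguous"] = amb.groupby(df["dup_group"]).any()
    out["rs439401"] = np.where(agg["t_nu"] == 1, agg["t_first"].fillna(-1), -1).astype(
        np.int64
    )

    has_seq = (agg["wgs_nu"] > 0) | (agg["wes_nu"] > 0)
    exclusion = np.full(len(out), NONE, dtype=object)
    exclusion[(agg["prov_nu"] > 1) & ~has_seq] = DUP_DISCORDANT_PROVIDED
    seq_internal = (agg["wgs_nu"] > 1) | (agg["wes_nu"] > 1)
    both = (agg["wgs_nu"] == 1) & (agg["wes_nu"] == 1)
    _, wgs_e4 = allele_counts_from_labels(out["wgs_apoe"].to_numpy(dtype=object))
    wgs_vs_wes = both.to_numpy() & (wgs_e4 != out["wes_c4"].to_numpy())
    exclusion[seq_internal.to_numpy() | wgs_vs_wes] = WGS_WES_DISCORDANT
    out["exclusion"] = exclusion

    out = out.reset_index()
    return out.sort_values("subject_id", kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# Adjudication
# ---------------------------------------------------------------------------

def adjudicate_approach1(subjects: pd.DataFrame) -> pd.DataFrame:
    """Assign one prioritized APOE genotype per subject.

    Priority: WGS, then a provided genotype (optionally verified against a
    WES rs429358 call — contradiction excludes the subject), imputation never.
    WES alone cannot separate e2 from e3, so WES-only subjects are NO_APOE.
    """
    df = subjects.copy()
    n = len(df)
    apoe = np.full(n, "", dtype=object)
    source = np.full(n, "", dtype=object)
    exclusion = df["exclusion"].to_numpy(dtype=object).copy()
    open_rows = exclusion == NONE

    wgs = df["wgs_apoe"].to_numpy(dtype=object)
    provided = df["provided"].to_numpy(dtype=object)
    wes_c4 = df["wes_c4"].to_numpy()

    use_wgs = open_rows & (wgs != "")
    apoe[use_wgs] = wgs[use_wgs]
    source[use_wgs] = "WGS"

    use_prov = open_rows & ~use_wgs & (provided != "")
    e2p, e4p = allele_counts_from_labels(provided)
    verifiable = use_prov & (wes_c4 >= 0) & (e2p == 0)
    contradicted = verifiable & (e4p != wes_c4)
    exclusion[contradicted] = WES_CONTRADICTED
    keep_prov = use_prov & ~contradicted
    apoe[keep_prov] = provided[keep_prov]
    source[keep_prov] = "PROVIDED"

    no_apoe = open_rows & ~use_wgs & ~use_prov
    exclusion[no_apoe] = NO_APOE

    df["apoe"] = apoe
    df["apoe_source"] = source
    df["wes_verified"] = verifiable & ~contradicted
    df["exclusion"] = exclusion
    return df


def adjudicate_approach2(
    subjects: pd.DataFrame, discordant_policy: str = "exclude"
) -> pd.DataFrame:
    """Apply the stringent imputation-concordance filter on top of approach 1.

    Subjects whose prioritized genotype is provided-sourced and differs from a
    usable imputed genotype are excluded (default) or, under
    ``discordant_policy="impute"``, re-assigned their imputed genotype.
    Subjects with a ``new_seq_apoe`` column entry contradicting their
    prioritized genotype are excluded regardless of source.
    """
    if discordant_policy not in ("exclude", "impute"):
        raise ValueError("discordant_policy must be 'exclude' or 'impute'")
    df = subjects.copy()
    exclusion = df["exclusion"].to_numpy(dtype=object).copy()
    apoe = df["apoe"].to_numpy(dtype=object).copy()
    source = df["apoe_source"].to_numpy(dtype=object).copy()
    open_rows = exclusion == NONE

    if "new_seq_apoe" in df.columns:
        new_seq = df["new_seq_apoe"].fillna("").to_numpy(dtype=object)
        contra = open_rows & (new_seq != "") & (apoe != "") & (new_seq != apoe)
        exclusion[contra] = NEW_SEQ_DISCORDANT
        open_rows = exclusion == NONE

    imputed = df["imputed"].to_numpy(dtype=object)
    discordant = (
        open_rows & (source == "PROVIDED") & (imputed != "") & (imputed != apoe)
    )
    if discordant_policy == "exclude":
        exclusion[discordant] = APPROACH2_IMPUTED_DISCORDANT
    else:
        apoe[discordant] = imputed[discordant]
        source[discordant] = "IMPUTED"

    df["apoe"] = apoe
    df["apoe_source"] = source
    df["exclusion"] = exclusion
    return df


def apply_inclusion_filters(
    subjects: pd.DataFrame, min_age: float = 60.0
) -> pd.DataFrame:
    """Restrict to CN/AD subjects aged ``min_age`` and above (inclusive)."""
    df = subjects.copy()
    exclusion = df["exclusion"].to_numpy(dtype=object).copy()
    open_rows = exclusion == NONE
    too_young = open_rows & (df["age"].to_numpy() < min_age)
    exclusion[too_young] = AGE_FILTER
    open_rows = exclusion == NONE
    bad_dx = open_rows & ~df["dx"].isin(["CN", "AD"]).to_numpy()
    exclusion[bad_dx] = DX_FILTER
    df["exclusion"] = exclusion
    return df


def retained(subjects: pd.DataFrame) -> pd.DataFrame:
    """Analysis set: subjects with no exclusion flag."""
    return subjects.loc[subjects["exclusion"] == NONE]


def exclusion_ledger(subjects: pd.DataFrame) -> pd.DataFrame:
    """Counts per exclusion reason; reconciles to the input size."""
    counts = subjects["exclusion"].value_counts()
    rows = [{"reason": "RETAINED", "n": int(counts.get(NONE, 0))}]
    for reason in EXCLUSION_REASONS:
        rows.append({"reason": reason, "n": int(counts.get(reason, 0))})
    df = pd.DataFrame(rows)
    assert df["n"].sum() == len(subjects)
    return df


def run_adjudication(
    manifest: pd.DataFrame,
    vcf_calls: pd.DataFrame,
    dosages: pd.DataFrame,
    dup_pairs: pd.DataFrame,
    approach: int = 2,
    r2_min: float = 0.8,
    min_age: float = 60.0,
    discordant_policy: str = "exclude",
) -> pd.DataFrame:
    """Full pipeline: sources -> harmonization -> adjudication -> filters."""
    if approach not in (1, 2):
        raise ValueError("approach must be 1 or 2")
    samples = build_sample_table(manifest, vcf_calls, dosages, r2_min=r2_min)
    subjects = harmonize_duplicates(samples, dup_pairs)
    subjects = adjudicate_approach1(subjects)
    if approach == 2:
        subjects = adjudicate_approach2(subjects, discordant_policy=discordant_policy)
    return apply_inclusion_filters(subjects, min_age=min_age)
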