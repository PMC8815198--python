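"""Stratified genotype-concordance diagnostics.

Concordance between two APOE genotype sources (e.g. provided vs imputed) is
the fraction of subjects, among those with both sources non-missing, whose
unordered epsilon pairs agree exactly — no partial credit for sharing one
allele.  Rates are reported overall and per stratum (cohort, case/control
status, APOE genotype, rs439401 carrier status, or any cross-product), which
is how a cohort with unreliable provided genotypes, or the depressed
concordance of rare-genotype/common-phenotype cells such as e4/4 controls,
becomes visible.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import NoPairsError

LOW_N = 5  # strata below this size are reported but flagged


def pairwise_concordance(
    records: pd.DataFrame,
    source_a: str,
    source_b: str,
    strata: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Agreement rate between two genotype columns, per stratum.

    ``source_a``/``source_b`` name columns holding APOE labels ("" = missing).
    ``strata`` names grouping columns; None gives a single overall row.
    Strata with no comparable subjects get rate NA.
    """
    for col in (source_a, source_b):
        if col not in records.columns:
            raise KeyError(f"unknown source column {col!r}")
    df = records.copy()
    a = df[source_a].fillna("").astype(str)
    b = df[source_b].fillna("").astype(str)
    df["_comparable"] = (a != "") & (b != "")
    df["_agree"] = df["_comparable"] & (a == b)

    if strata:
        grouped = df.groupby(list(strata), dropna=False, observed=True)
        out = grouped.agg(
            n_compared=("_comparable", "sum"), n_agree=("_agree", "sum")
        ).reset_index()
        out["stratum"] = out[list(strata)].astype(str).agg("/".join, axis=1)
    else:
        out = pd.DataFrame(
            {
                "stratum": ["ALL"],
                "n_compared": [int(df["_comparable"].sum())],
                "n_agree": [int(df["_agree"].sum())],
            }
        )
    out["n_compared"] = out["n_compared"].astype(int)
    out["n_agree"] = out["n_agree"].astype(int)
    with np.errstate(invalid="ignore"):
        out["rate"] = np.where(
            out["n_compared"] > 0, out["n_agree"] / out["n_compared"], np.nan
        )
    out["low_n"] = out["n_compared"] < LOW_N
    cols = ["stratum", "n_compared", "n_agree", "rate", "low_n"]
    extra = [c for c in out.columns if c not in cols and not c.startswith("_")]
    return out[extra + cols]


def duplicate_variant_concordance(
    samples: pd.DataFrame,
    dup_pairs: pd.DataFrame,
    variant_col: str,
) -> pd.Series:
    """Fraction of duplicate pairs with identical unphased genotype at a site.

    ``variant_col`` holds ALT counts with negatives for missing. Pairs with a
    missing call on either side are not compared; no comparable pairs raises
    NoPairsError.
    """
    calls = samples.set_index("sample_id")[variant_col]
    a = dup_pairs["sample_id_a"].map(calls)
    b = dup_pairs["sample_id_b"].map(calls)
    ok = (a >= 0) & (b >= 0) & a.notna() & b.notna()
    n = int(ok.sum())
    if n == 0:
        raise NoPairsError(f"no duplicate pairs with non-missing {variant_col}")
    agree = int(((a == b) & ok).sum())
    return pd.Series(
        {"variant": variant_col, "n_compared": n, "n_agree": agree, "rate": agree / n}
    )


def concordance_report(
    subjects: pd.DataFrame,
    source_a: str = "provided",
    source_b: str = "imputed",
) -> pd.DataFrame:
    """Standard diagnostic battery: overall, per cohort, per dx, per APOE
    genotype x dx, and per rs439401-carrier x dx strata, stacked."""
    df = subjects.copy()
    df["rs439401_carrier"] = np.where(
        df["rs439401"] < 0, "NA", np.where(df["rs439401"] > 0, "carrier", "non-carrier")
    )
    blocks = []
    for name, strata in (
        ("overall", None),
        ("cohort", ["cohort"]),
        ("dx", ["dx"]),
        ("apoe_dx", ["apoe", "dx"]),
        ("carrier_dx", ["rs439401_carrier", "dx"]),
        ("apoe_carrier_dx", ["apoe", "rs439401_carrier", "dx"]),
    ):
        block = pairwise_concordance(df, source_a, source_b, strata)
        block.insert(0, "stratification", name)
        blocks.append(block[["stratification", "stratum", "n_compared", "n_agree", "rate", "low_n"]])
    return pd.concat(blocks, ignore_index=True)
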