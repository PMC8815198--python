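"""Stratified case-control association analyses.

Each stratum (built by :func:`apoeqc.ld.assign_strata`) is analysed with a
logistic regression of AD status on the stratum's genotype coding plus age,
sex and the first five principal components; the full-sample design adds e2
and e4 allele dosages, and a cohort-adjusted sensitivity mode adds cohort
fixed effects. Inference is Wald throughout: OR = exp(beta), 95% CI =
exp(beta +/- 1.96 se), significance threshold P < 0.05.

A crude cross-product odds ratio (with Haldane-Anscombe 0.5 correction when
any cell is empty) accompanies the adjusted models as a sanity check.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import EmptyStratumError, NoVariationError, SeparationError
from . import ld

Z95 = 1.959963984540054

ADDITIVE_LOGISTIC = "ADDITIVE_LOGISTIC"
WT_HOM_LOGISTIC = "WT_HOM_LOGISTIC"
CRUDE_2X2 = "CRUDE_2x2"

DEFAULT_COVARIATES = ("age", "sex") + tuple(f"PC{k+1}" for k in range(5))


@dataclass
class StratumResult:
    """Counts, frequencies and effect estimate for one APOE stratum."""

    stratum: str
    model: str
    n_cn: int
    n_ad: int
    carriers_cn: int
    carriers_ad: int
    maf_cn: float
    maf_ad: float
    or_: float
    ci_low: float
    ci_high: float
    p: float
    note: str = ""

    @property
    def significant(self) -> bool:
        return bool(self.p < 0.05)

    def as_dict(self) -> dict:
        d = {
            "stratum": self.stratum,
            "model": self.model,
            "n_CN": self.n_cn,
            "n_AD": self.n_ad,
            "carriers_CN": self.carriers_cn,
            "carriers_AD": self.carriers_ad,
            "maf_CN": self.maf_cn,
            "maf_AD": self.maf_ad,
            "OR": self.or_,
            "CI95_low": self.ci_low,
            "CI95_high": self.ci_high,
            "P": self.p,
            "note": self.note,
        }
        return d


def carrier_table(df: pd.DataFrame, geno_col: str = "rs439401") -> pd.DataFrame:
    """Carrier counts/percentages (>= 1 T allele) and allelic MAF per phenotype.

    Percentages are rounded to two decimals, matching the reporting
    convention "carrier No. / Total No. (%)".
    """
    if len(df) == 0:
        raise EmptyStratumError("no subjects in stratum")
    rows = []
    for dx in ("CN", "AD"):
        sub = df.loc[df["dx"] == dx]
        t = sub[geno_col].to_numpy()
        t = t[t >= 0]
        n = len(t)
        carriers = int((t > 0).sum())
        rows.append(
            {
                "dx": dx,
                "n": n,
                "carriers": carriers,
                "carrier_pct": round(100.0 * carriers / n, 2) if n else float("nan"),
                "maf": (t.sum() / (2 * n)) if n else float("nan"),
            }
        )
    return pd.DataFrame(rows)


def crude_or(
    a: float, b: float, c: float, d: float, correction: bool = True
) -> StratumResult:
    """Cross-product OR for a 2x2 table (exposed/unexposed x AD/CN).

    ``a``/``b`` are exposed/unexposed cases, ``c``/``d`` exposed/unexposed
    controls. When any cell is zero and ``correction`` is set, 0.5 is added
    to every cell (Haldane-Anscombe).
    """
    cells = np.array([a, b, c, d], dtype=float)
    if np.any(cells < 0):
        raise ValueError("negative cell count")
    if cells[0] + cells[2] == 0 and cells[1] + cells[3] == 0:
        raise EmptyStratumError("all margins zero")
    note = ""
    if np.any(cells == 0):
        if not correction:
            raise ZeroDivisionError("zero cell without correction")
        cells = cells + 0.5
        note = "haldane-anscombe 0.5 applied"
    a_, b_, c_, d_ = cells
    log_or = math.log(a_ * d_ / (b_ * c_))
    se = math.sqrt(1 / a_ + 1 / b_ + 1 / c_ + 1 / d_)
    p = 2 * (1 - _norm_cdf(abs(log_or) / se))
    return StratumResult(
        stratum="2x2",
        model=CRUDE_2X2,
        n_cn=int(c + d),
        n_ad=int(a + b),
        carriers_cn=int(c),
        carriers_ad=int(a),
        maf_cn=float("nan"),
        maf_ad=float("nan"),
        or_=math.exp(log_or),
        ci_low=math.exp(log_or - Z95 * se),
        ci_high=math.exp(log_or + Z95 * se),
        p=p,
        note=note,
    )


def _norm_cdf(x: float) -> float:
    return 0.5 * (1.0 + math.erf(x / math.sqrt(2.0)))


def fit_stratum(
    df: pd.DataFrame,
    stratum: str,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    cohort_adjust: bool = False,
    extra_dosage: bool = False,
) -> StratumResult:
    """Logistic regression of AD status on the genotype coding ``g``.

    ``extra_dosage`` adds e2_dosage/e4_dosage columns (full-sample design);
    ``cohort_adjust`` adds cohort fixed effects (sensitivity analysis; the
    primary mega-analysis design pools cohorts without adjustment).

    Raises NoVariationError for a constant genotype column and
    SeparationError when the fit is degenerate (non-finite or absurdly large
    standard error), with advice to inspect the carrier counts.
    """
    sub = df.loc[df["g"].notna() & df["dx"].isin(["CN", "AD"])].copy()
    if len(sub) == 0 or (sub["dx"] == "CN").sum() == 0 or (sub["dx"] == "AD").sum() == 0:
        raise EmptyStratumError(f"{stratum}: need at least one case and one control")
    g = sub["g"].to_numpy(dtype=float)
    if np.all(g == g[0]):
        raise NoVariationError(f"{stratum}: genotype coding is constant")

    y = (sub["dx"] == "AD").to_numpy(dtype=float)
    X = pd.DataFrame({"g": g}, index=sub.index)
    for cov in covariates:
        if cov == "sex":
            X["sex"] = (sub["sex"] == "F").astype(float)
        else:
            X[cov] = sub[cov].astype(float)
    if extra_dosage:
        X["e2_dosage"] = sub["e2_dosage"].astype(float)
        X["e4_dosage"] = sub["e4_dosage"].astype(float)
    if cohort_adjust:
        dummies = pd.get_dummies(sub["cohort"], prefix="cohort", drop_first=True)
        X = pd.concat([X, dummies.astype(float)], axis=1)
    X = sm.add_constant(X, has_constant="add")

    try:
        with warnings.catch_warnings():
            # near-empty cells in rare-genotype strata trip harmless
            # convergence warnings; degenerate fits are caught below
            warnings.simplefilter("ignore")
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
    except Exception as exc:  # statsmodels raises PerfectSeparationError et al.
        raise SeparationError(
            f"{stratum}: logistic fit failed ({exc}); inspect carrier counts "
            "before interpreting this stratum"
        ) from exc
    beta = fit.params["g"]
    se = fit.bse["g"]
    if not (np.isfinite(beta) and np.isfinite(se)) or se > 50:
        raise SeparationError(
            f"{stratum}: separation suspected (beta={beta:.3g}, se={se:.3g}); "
            "inspect carrier counts"
        )

    ct = carrier_table(sub, geno_col="g") if "rs439401" not in sub else carrier_table(sub)
    cn = ct.loc[ct["dx"] == "CN"].iloc[0]
    ad = ct.loc[ct["dx"] == "AD"].iloc[0]
    model = WT_HOM_LOGISTIC if stratum == ld.E34_WT_VS_HOM else ADDITIVE_LOGISTIC
    return StratumResult(
        stratum=stratum,
        model=model,
        n_cn=int((sub["dx"] == "CN").sum()),
        n_ad=int((sub["dx"] == "AD").sum()),
        carriers_cn=int(cn["carriers"]),
        carriers_ad=int(ad["carriers"]),
        maf_cn=float(cn["maf"]),
        maf_ad=float(ad["maf"]),
        or_=math.exp(beta),
        ci_low=math.exp(beta - Z95 * se),
        ci_high=math.exp(beta + Z95 * se),
        p=float(fit.pvalues["g"]),
    )


def analyse_strata(
    subjects: pd.DataFrame,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    cohort_adjust: bool = False,
    strata: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Fit every association design on an adjudicated analysis set.

    Strata that cannot be fitted (empty, constant genotype, separation) get a
    row with NA estimates and the failure note — reported, never dropped.
    """
    designs = ld.assign_strata(subjects)
    rows = []
    for name in strata or ld.STRATA:
        sub = designs[name]
        try:
            res = fit_stratum(
                sub,
                name,
                covariates=covariates,
                cohort_adjust=cohort_adjust,
                extra_dosage=(name == ld.FULL_ADJUSTED),
            )
            rows.append(res.as_dict())
        except (EmptyStratumError, NoVariationError, SeparationError) as exc:
            rows.append(
                {
                    "stratum": name,
                    "model": "NA",
                    "n_CN": int((sub["dx"] == "CN").sum()),
                    "n_AD": int((sub["dx"] == "AD").sum()),
                    "carriers_CN": int(((sub["dx"] == "CN") & (sub["g"] > 0)).sum()),
                    "carriers_AD": int(((sub["dx"] == "AD") & (sub["g"] > 0)).sum()),
                    "maf_CN": float("nan"),
                    "maf_AD": float("nan"),
                    "OR": float("nan"),
                    "CI95_low": float("nan"),
                    "CI95_high": float("nan"),
                    "P": float("nan"),
                    "note": f"{type(exc).__name__}: {exc}",
                }
            )
    return pd.DataFrame(rows)


def compare_approaches(
    subjects_a1: pd.DataFrame,
    subjects_a2: pd.DataFrame,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    cohort_adjust: bool = False,
) -> pd.DataFrame:
    """Paired approach-1 vs approach-2 rows per stratum, with carrier-frequency
    deltas — the side-by-side view of how the stringent filter changes the
    association picture."""
    r1 = analyse_strata(subjects_a1, covariates, cohort_adjust)
    r2 = analyse_strata(subjects_a2, covariates, cohort_adjust)
    r1.insert(0, "approach", 1)
    r2.insert(0, "approach", 2)
    out = pd.concat([r1, r2], ignore_index=True).sort_values(
        ["stratum", "approach"], kind="stable"
    )
    for dx in ("CN", "AD"):
        out[f"carrier_freq_{dx}"] = out[f"carriers_{dx}"] / out[f"n_{dx}"].replace(0, np.nan)
    deltas = (
        out.pivot_table(index="stratum", columns="approach", values="carrier_freq_CN")
        .rename(columns={1: "a1", 2: "a2"})
    )
    if {"a1", "a2"} <= set(deltas.columns):
        delta = (deltas["a2"] - deltas["a1"]).rename("carrier_freq_CN_delta")
        out = out.merge(delta, left_on="stratum", right_index=True, how="left")
    return out.reset_index(drop=True)
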