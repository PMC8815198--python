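"""Closed-form model of APOE*4/4 genotype misclassification.

The model asks: if a fraction ``f_true`` of a phenotype group (cases or
controls) are genuinely e4/4, and genotyping mislabels non-carriers as e4/4
with probability ``p1`` (type I) and carriers as non-e4/4 with probability
``p2`` (type II), what fraction of *observed* e4/4 labels are real?

    f_obs       = f_true * (1 - p2) + (1 - f_true) * p1
    concordance = f_true * (1 - p2) / f_obs

Because e4/4 is rare among controls (~2%) but common among cases (~13%),
identical error rates dilute the observed control carriers far more than the
case carriers: the concordance is increasing in f_true whenever p1 > 0.  This
is the mechanism by which symmetric genotyping error manufactures spurious
protective associations for anything riding along with e4/4 in controls.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DomainError


@dataclass(frozen=True)
class MisclassModel:
    """(f_true, p1, p2) triple; all probabilities."""

    f_true: float
    p1: float
    p2: float

    def __post_init__(self) -> None:
        if not 0.0 < self.f_true < 1.0:
            raise DomainError(f"f_true {self.f_true} outside (0, 1)")
        for name in ("p1", "p2"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise DomainError(f"{name} {v} outside [0, 1]")


def observed_frequency(m: MisclassModel) -> float:
    """Observed e4/4 frequency under the error model."""
    return m.f_true * (1.0 - m.p2) + (1.0 - m.f_true) * m.p1


def concordance_observed_true(m: MisclassModel) -> float:
    """P(truly e4/4 | observed e4/4).

    Raises ZeroDivisionError when no carriers are observed (f_obs = 0).
    """
    f_obs = observed_frequency(m)
    if f_obs == 0.0:
        raise ZeroDivisionError("f_obs is zero: no observed e4/4 carriers")
    return m.f_true * (1.0 - m.p2) / f_obs


def monte_carlo_concordance(m: MisclassModel, n: int, seed: int) -> float:
    """Simulation cross-check of the closed form.

    Draws ``n`` subjects with true status Bernoulli(f_true), applies the two
    flip probabilities, and returns the empirical fraction of observed e4/4
    labels that are true. Returns NaN when no subject is observed as e4/4.
    """
    if n < 1:
        raise DomainError("n must be >= 1")
    rng = np.random.default_rng(seed)
    true = rng.random(n) < m.f_true
    u = rng.random(n)
    observed = np.where(true, u >= m.p2, u < m.p1)
    n_obs = int(observed.sum())
    if n_obs == 0:
        return float("nan")
    return float((true & observed).sum() / n_obs)


def sweep_grid(
    f_true_values,
    p1_values,
    p2_values=None,
) -> pd.DataFrame:
    """Concordance over a grid of error rates and true frequencies.

    Returns a tidy table with columns f_true, p1, p2, f_obs, concordance.
    ``p2_values`` defaults to ``p1_values``.
    """
    f_true_values = np.atleast_1d(np.asarray(f_true_values, dtype=float))
    p1_values = np.atleast_1d(np.asarray(p1_values, dtype=float))
    p2_values = (
        p1_values if p2_values is None else np.atleast_1d(np.asarray(p2_values, float))
    )
    if f_true_values.size == 0 or p1_values.size == 0 or p2_values.size == 0:
        raise DomainError("grid ranges must be non-empty")
    rows = []
    for f in f_true_values:
        for p1 in p1_values:
            for p2 in p2_values:
                m = MisclassModel(float(f), float(p1), float(p2))
                f_obs = observed_frequency(m)
                conc = (
                    float("nan") if f_obs == 0.0 else concordance_observed_true(m)
                )
                rows.append(
                    {"f_true": f, "p1": p1, "p2": p2, "f_obs": f_obs, "concordance": conc}
                )
    return pd.DataFrame(rows)


#: Default true e4/4 frequencies bracketing what large case-control samples
#: show: ~1.9% of controls and ~12.9% of cases are e4/4.
DEFAULT_F_TRUE_CONTROL = 0.019
DEFAULT_F_TRUE_CASE = 0.129
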