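"""EM haplotype-frequency estimation, D', and phase-guaranteed strata."""

import numpy as np
import pandas as pd
import pytest

from apoeqc import em_haplotype_freqs, dprime
from apoeqc.errors import EmptyTableError, MonomorphicError
from apoeqc import ld


def random_table(rng, n=40):
    """Draw a genotype table from random haplotype frequencies."""
    f = rng.dirichlet([1.0, 1.0, 1.0, 1.0])
    haps = rng.choice(4, size=(n, 2), p=f)
    # hap codes: 0=AB, 1=Ab, 2=aB, 3=ab
    a = (haps < 2).sum(axis=1)
    b = ((haps == 0) | (haps == 2)).sum(axis=1)
    return ld.genotype_table(a, b)


def grid_search_mle(counts, steps=20001):
    """Independent oracle: profile the likelihood over the one free haplotype
    frequency (allele margins are fixed by the genotype counts)."""
    counts = np.asarray(counts, dtype=float)
    n = counts.sum()
    p_a = (counts.sum(axis=1) @ np.arange(3)) / (2 * n)
    p_b = (counts.sum(axis=0) @ np.arange(3)) / (2 * n)
    lo, hi = max(0.0, p_a + p_b - 1.0), min(p_a, p_b)
    best_ll, best = -np.inf, None
    for hab in np.linspace(lo, hi, steps):
        f = np.array([hab, p_a - hab, p_b - hab, 1 - p_a - p_b + hab])
        if (f < -1e-12).any():
            continue
        llv = ld.loglik_table(counts, np.clip(f, 1e-12, None))
        if llv > best_ll:
            best_ll, best = llv, hab
    return best, best_ll


class TestEM:
    def test_no_double_het_equals_direct_counting(self):
        # without the (1,1) cell the phase is fully observed
        counts = np.array([[5, 2, 1], [3, 0, 2], [1, 4, 6]])
        h = em_haplotype_freqs(counts)
        n = counts.sum()
        expected_ab = (
            2 * counts[2, 2] + counts[2, 1] + counts[1, 2]
        ) / (2 * n)
        assert h.p_AB == pytest.approx(expected_ab, abs=1e-9)
        assert h.as_array().sum() == pytest.approx(1.0, abs=1e-12)

    def test_empty_table(self):
        with pytest.raises(EmptyTableError):
            em_haplotype_freqs(np.zeros((3, 3)))

    @pytest.mark.parametrize("trial", range(12))
    def test_matches_grid_search_oracle(self, trial):
        rng = np.random.default_rng(1000 + trial)
        counts = random_table(rng, n=40)
        if counts.sum(axis=1) @ np.arange(3) in (0, 2 * counts.sum()):
            pytest.skip("monomorphic draw")
        h = em_haplotype_freqs(counts)
        hab, ll = grid_search_mle(counts)
        # same optimum: frequency within grid resolution or equal likelihood
        assert (abs(h.p_AB - hab) < 5e-4) or (h.loglik >= ll - 1e-9)

    @pytest.mark.parametrize("trial", range(8))
    def test_loglik_monotone_and_simplex(self, trial):
        rng = np.random.default_rng(2000 + trial)
        counts = random_table(rng, n=60)
        h = em_haplotype_freqs(counts)
        path = np.array(h.loglik_path)
        assert (np.diff(path) > -1e-9).all()
        assert abs(h.as_array().sum() - 1.0) < 1e-12
        assert (h.as_array() >= 0).all()


class TestDprime:
    def _freqs(self, fab, fAb, faB, faa):
        return ld.HaplotypeFreqs(fab, fAb, faB, faa, 0.0, 1, 100)

    def test_perfect_coupling(self):
        h = self._freqs(0.3, 0.0, 0.0, 0.7)
        assert dprime(h) == pytest.approx(1.0)

    def test_independence(self):
        h = self._freqs(0.12, 0.18, 0.28, 0.42)  # p_A=0.3, p_B=0.4, D=0
        assert dprime(h) == pytest.approx(0.0, abs=1e-12)

    def test_negative_d_sign(self):
        h = self._freqs(0.05, 0.45, 0.45, 0.05)
        assert dprime(h) < 0

    def test_bounded(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            f = rng.dirichlet([1, 1, 1, 1])
            h = self._freqs(*f)
            if min(h.p_A, 1 - h.p_A, h.p_B, 1 - h.p_B) <= 0:
                continue
            assert -1.0 - 1e-9 <= dprime(h) <= 1.0 + 1e-9

    def test_monomorphic_raises(self):
        with pytest.raises(MonomorphicError):
            dprime(self._freqs(0.6, 0.4, 0.0, 0.0))


class TestAssignStrata:
    @pytest.fixture()
    def subjects(self):
        rows = [
            ("e4/e4", 0), ("e4/e4", 1), ("e4/e4", 2),
            ("e3/e4", 0), ("e3/e4", 1), ("e3/e4", 2),
            ("e3/e3", 1), ("e2/e4", 2), ("e2/e3", 0),
            ("e3/e4", -1),  # missing rs439401
        ]
        return pd.DataFrame(
            {
                "subject_id": [f"S{i}" for i in range(len(rows))],
                "apoe": [r[0] for r in rows],
                "rs439401": [r[1] for r in rows],
                "dx": ["CN"] * len(rows),
            }
        )

    def test_e44_additive_codes_t_count(self, subjects):
        s = ld.assign_strata(subjects)[ld.E44_ADDITIVE]
        assert list(s["g"]) == [0.0, 1.0, 2.0]  # a single T is in phase with e4

    def test_wt_vs_hom_drops_heterozygotes(self, subjects):
        s = ld.assign_strata(subjects)[ld.E34_WT_VS_HOM]
        assert set(s["rs439401"]) == {0, 2}
        assert list(s["g"]) == [0.0, 1.0]

    def test_e24_absent_from_genotype_strata(self, subjects):
        strata = ld.assign_strata(subjects)
        for name in (ld.E44_ADDITIVE, ld.E34_WT_VS_HOM, ld.E34_ADDITIVE, ld.E33_ADDITIVE):
            assert not (strata[name]["apoe"] == "e2/e4").any()

    def test_full_design_has_dosage_covariates(self, subjects):
        full = ld.assign_strata(subjects)[ld.FULL_ADJUSTED]
        row = full.loc[full["apoe"] == "e2/e4"].iloc[0]
        assert row["e2_dosage"] == 1.0 and row["e4_dosage"] == 1.0
        # missing rs439401 excluded everywhere
        assert (full["rs439401"] >= 0).all()
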