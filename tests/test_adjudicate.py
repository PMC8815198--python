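"""Duplicate harmonization, approach-1/2 adjudication, and inclusion filters."""

import numpy as np
import pandas as pd
import pytest

from apoeqc import adjudicate as adj
from apoeqc.errors import MissingSampleError
from apoeqc.simulate import CohortSpec, SimConfig, simulate_dataset
from apoeqc.experiments import run_both_approaches


def make_samples(rows):
    """Minimal sample table: (sample_id, provided, wgs, wes_c4, imputed, age, dx)."""
    base = {
        "cohort": "C",
        "sex": "F",
        **{f"PC{k+1}": 0.0 for k in range(5)},
        "wgs_inconsistent": False,
        "imputed_ambiguous": False,
        "rs439401": 0,
    }
    recs = []
    for r in rows:
        rec = dict(base)
        rec.update(
            sample_id=r[0],
            subject_id=r[0].split("_")[0],
            provided=r[1],
            wgs_apoe=r[2],
            wes_c4=r[3],
            imputed=r[4],
            age=r[5] if len(r) > 5 else 70.0,
            dx=r[6] if len(r) > 6 else "CN",
        )
        recs.append(rec)
    return pd.DataFrame(recs)


def pairs(*ab):
    return pd.DataFrame(ab, columns=["sample_id_a", "sample_id_b"])


class TestHarmonizeDuplicates:
    def test_provided_only_discordant_flagged(self):
        s = make_samples([("A_s0", "e3/e3", "", -1, ""), ("A_s1", "e3/e4", "", -1, "")])
        out = adj.harmonize_duplicates(s, pairs(("A_s0", "A_s1")))
        assert len(out) == 1
        assert out.loc[0, "exclusion"] == adj.DUP_DISCORDANT_PROVIDED

    def test_concordant_duplicates_merge_cleanly(self):
        s = make_samples([("A_s0", "e3/e4", "", -1, ""), ("A_s1", "e3/e4", "", -1, "")])
        out = adj.harmonize_duplicates(s, pairs(("A_s0", "A_s1")))
        assert out.loc[0, "exclusion"] == adj.NONE
        assert out.loc[0, "provided"] == "e3/e4"
        assert out.loc[0, "n_samples"] == 2

    def test_wgs_wes_contradiction_flagged(self):
        # WES sees one e4 arm, WGS says e3/e3: sequencing self-contradiction
        s = make_samples([("A_s0", "", "e3/e3", -1, ""), ("A_s1", "", "", 1, "")])
        out = adj.harmonize_duplicates(s, pairs(("A_s0", "A_s1")))
        assert out.loc[0, "exclusion"] == adj.WGS_WES_DISCORDANT

    def test_sequencing_overrides_provided_discordance(self):
        s = make_samples([("A_s0", "e3/e3", "e3/e4", -1, ""), ("A_s1", "e3/e4", "", -1, "")])
        out = adj.harmonize_duplicates(s, pairs(("A_s0", "A_s1")))
        assert out.loc[0, "exclusion"] == adj.NONE
        assert out.loc[0, "wgs_apoe"] == "e3/e4"

    def test_transitive_closure(self):
        s = make_samples(
            [("A_s0", "e3/e3", "", -1, ""), ("A_s1", "e3/e3", "", -1, ""),
             ("A_s2", "e3/e3", "", -1, "")]
        )
        out = adj.harmonize_duplicates(s, pairs(("A_s0", "A_s1"), ("A_s1", "A_s2")))
        assert len(out) == 1 and out.loc[0, "n_samples"] == 3

    def test_unknown_sample_raises(self):
        s = make_samples([("A_s0", "e3/e3", "", -1, "")])
        with pytest.raises(MissingSampleError):
            adj.harmonize_duplicates(s, pairs(("A_s0", "GHOST")))


class TestApproach1:
    def test_wgs_beats_provided(self):
        s = make_samples([("A_s0", "e3/e4", "e4/e4", -1, "")])
        out = adj.adjudicate_approach1(adj.harmonize_duplicates(s, pairs()))
        assert out.loc[0, "apoe"] == "e4/e4"
        assert out.loc[0, "apoe_source"] == "WGS"

    def test_imputation_entirely_ignored(self):
        s = make_samples([("A_s0", "e3/e4", "", -1, "e3/e3")])
        out = adj.adjudicate_approach1(adj.harmonize_duplicates(s, pairs()))
        assert out.loc[0, "apoe"] == "e3/e4"
        assert out.loc[0, "exclusion"] == adj.NONE

    def test_wes_contradiction_excludes(self):
        s = make_samples([("A_s0", "e4/e4", "", 1, "")])
        out = adj.adjudicate_approach1(adj.harmonize_duplicates(s, pairs()))
        assert out.loc[0, "exclusion"] == adj.WES_CONTRADICTED

    def test_wes_confirmation_keeps_provided(self):
        s = make_samples([("A_s0", "e3/e4", "", 1, "")])
        out = adj.adjudicate_approach1(adj.harmonize_duplicates(s, pairs()))
        assert out.loc[0, "apoe"] == "e3/e4"
        assert bool(out.loc[0, "wes_verified"])

    def test_wes_only_subject_is_no_apoe(self):
        # WES cannot separate e2 from e3, so nothing to prioritize
        s = make_samples([("A_s0", "", "", 2, "")])
        out = adj.adjudicate_approach1(adj.harmonize_duplicates(s, pairs()))
        assert out.loc[0, "exclusion"] == adj.NO_APOE


class TestApproach2:
    def _adjud(self, s, policy="exclude"):
        a1 = adj.adjudicate_approach1(adj.harmonize_duplicates(s, pairs()))
        return adj.adjudicate_approach2(a1, discordant_policy=policy)

    def test_provided_imputed_discordance_excludes(self):
        s = make_samples([("A_s0", "e4/e4", "", -1, "e3/e4")])
        out = self._adjud(s)
        assert out.loc[0, "exclusion"] == adj.APPROACH2_IMPUTED_DISCORDANT

    def test_concordant_kept(self):
        s = make_samples([("A_s0", "e3/e4", "", -1, "e3/e4")])
        assert self._adjud(s).loc[0, "exclusion"] == adj.NONE

    def test_sequencing_immune_to_imputation(self):
        s = make_samples([("A_s0", "", "e3/e4", -1, "e3/e3")])
        out = self._adjud(s)
        assert out.loc[0, "exclusion"] == adj.NONE
        assert out.loc[0, "apoe"] == "e3/e4"

    def test_impute_policy_reassigns_instead_of_excluding(self):
        s = make_samples([("A_s0", "e4/e4", "", -1, "e3/e4")])
        out = self._adjud(s, policy="impute")
        assert out.loc[0, "exclusion"] == adj.NONE
        assert out.loc[0, "apoe"] == "e3/e4"
        assert out.loc[0, "apoe_source"] == "IMPUTED"

    def test_new_seq_contradiction_excludes(self):
        s = make_samples([("A_s0", "e4/e4", "", -1, "e4/e4")])
        a1 = adj.adjudicate_approach1(adj.harmonize_duplicates(s, pairs()))
        a1["new_seq_apoe"] = ["e3/e4"]
        out = adj.adjudicate_approach2(a1)
        assert out.loc[0, "exclusion"] == adj.NEW_SEQ_DISCORDANT


class TestInclusionFilters:
    @pytest.mark.parametrize(
        "age, dx, expected",
        [
            (59.9, "CN", adj.AGE_FILTER),
            (60.0, "CN", adj.NONE),  # "aged 60 and above" is inclusive
            (75.0, "MCI", adj.DX_FILTER),
            (75.0, "AD", adj.NONE),
        ],
    )
    def test_age_and_dx(self, age, dx, expected):
        s = make_samples([("A_s0", "e3/e3", "", -1, "", age, dx)])
        out = adj.apply_inclusion_filters(
            adj.adjudicate_approach1(adj.harmonize_duplicates(s, pairs()))
        )
        assert out.loc[0, "exclusion"] == expected


class TestPipelineProperties:
    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_approach2_subset_of_approach1(self, seed):
        rng = np.random.default_rng(seed)
        cfg = SimConfig(
            seed=seed,
            cohorts=(
                CohortSpec("X", 300, "array", float(rng.uniform(0, 0.1))),
                CohortSpec("Y", 200, rng.choice(["array", "wgs", "wes"]), 0.02),
            ),
            dup_rate=float(rng.uniform(0, 0.1)),
            imputation_error_rate=float(rng.uniform(0, 0.05)),
            wgs_error_rate=float(rng.uniform(0, 0.02)),
        )
        ds = simulate_dataset(cfg)
        s1, s2 = run_both_approaches(ds)
        kept1 = set(adj.retained(s1)["subject_id"])
        kept2 = set(adj.retained(s2)["subject_id"])
        assert kept2 <= kept1

    def test_exclusion_counts_reconcile(self, small_dataset):
        s1, s2 = run_both_approaches(small_dataset)
        for s in (s1, s2):
            ledger = adj.exclusion_ledger(s)
            assert ledger["n"].sum() == len(s)

    def test_zero_error_limit_identical_sets(self):
        cfg = SimConfig(
            seed=17,
            cohorts=(
                CohortSpec("X", 800, "array", 0.0),
                CohortSpec("Y", 300, "wgs", 0.0),
            ),
            dup_rate=0.05,
            imputation_error_rate=0.0,
            wgs_error_rate=0.0,
            provided_missing_rate=0.0,
        )
        ds = simulate_dataset(cfg)
        s1, s2 = run_both_approaches(ds)
        assert (s1["exclusion"].isin([adj.NONE, adj.AGE_FILTER])).all()
        pd.testing.assert_frame_equal(adj.retained(s1), adj.retained(s2))

    def test_approach2_purges_planted_errors(self):
        # provided errors + accurate imputation: approach 2 retains a
        # strictly cleaner set
        cfg = SimConfig(
            seed=23,
            cohorts=(CohortSpec("X", 6000, "array", 0.05),),
            imputation_error_rate=0.001,
        )
        ds = simulate_dataset(cfg)
        truth = ds.truth.set_index("subject_id")["apoe_true"]
        s1, s2 = run_both_approaches(ds)
        errs = {}
        for name, s in (("a1", s1), ("a2", s2)):
            kept = adj.retained(s)
            errs[name] = (
                kept["apoe"].to_numpy(dtype=object)
                != truth.loc[kept["subject_id"]].to_numpy(dtype=object)
            ).mean()
        assert errs["a2"] < errs["a1"]
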