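"""Harmonisation rules: MAF annotation, rescaling, power, qualification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from pleiomap.harmonise import (
    CredibleSet,
    StudyRecord,
    annotate_major_ancestry_maf,
    assign_therapeutic_area,
    compute_power,
    effective_sample_size,
    filter_lead_variants_for_consequence_analysis,
    flag_replication,
    major_ancestry,
    qualify_credible_sets,
    qualify_studies,
    rescale_effect,
    resolve_most_severe,
    z_from_p,
)


def _study(**kw):
    base = dict(study_id="S1", study_type="disease", trait_id="EFO:1",
                n=10_000, n_cases=2_000)
    base.update(kw)
    return StudyRecord(**base)


class TestMafAnnotation:
    def test_single_population_min_of_eaf(self):
        st_ = _study(ancestry_composition={"NFE": 1.0})
        tab = pd.DataFrame({"variant_id": ["v1"], "eaf_NFE": [0.8]})
        assert annotate_major_ancestry_maf(st_, "v1", tab) == pytest.approx(0.2)

    def test_even_tie_prefers_nfe(self):
        st_ = _study(ancestry_composition={"EAS": 0.5, "NFE": 0.5})
        assert major_ancestry(st_.ancestry_composition) == "NFE"
        st2 = _study(ancestry_composition={"EAS": 0.5, "AFR": 0.5})
        assert major_ancestry(st2.ancestry_composition) == "EAS"  # first listed

    def test_largest_proportion_wins(self):
        assert major_ancestry({"EAS": 0.7, "NFE": 0.3}) == "EAS"

    def test_absent_variant_is_failed_annotation(self):
        st_ = _study()
        tab = pd.DataFrame({"variant_id": ["v1"], "eaf_NFE": [0.2]})
        assert annotate_major_ancestry_maf(st_, "v2", tab) is None

    def test_empty_composition_fails(self):
        with pytest.raises(ValueError):
            major_ancestry({})


class TestRescaleEffect:
    def test_quantitative_se_closed_form(self):
        se, _ = rescale_effect(p=0.5, sign="+", n=10_000, f=0.5)
        assert se == pytest.approx(1.0 / np.sqrt(5000), rel=1e-12)

    def test_p_near_one_gives_null_beta(self):
        _, beta = rescale_effect(p=0.999999, sign="+", n=10_000, f=0.3)
        assert abs(beta) < 1e-4

    def test_binary_se_includes_case_fraction(self):
        se_b, _ = rescale_effect(p=0.01, sign="-", n=10_000, f=0.2, K=0.1,
                                 trait_type="binary")
        expect = 1.0 / np.sqrt(2 * 10_000 * 0.2 * 0.8 * 0.1 * 0.9)
        assert se_b == pytest.approx(expect, rel=1e-12)

    def test_sign_applied(self):
        _, bp = rescale_effect(p=0.001, sign="+", n=10_000, f=0.2)
        _, bm = rescale_effect(p=0.001, sign="-", n=10_000, f=0.2)
        assert bp > 0 and bm == pytest.approx(-bp)

    def test_underflowing_p_uses_log_pathway(self):
        z1 = z_from_p(log10_p=-320.0)
        z2 = z_from_p(log10_p=-321.0)
        assert np.isfinite(z1) and z2 > z1 > 38

    def test_p_zero_rejected(self):
        with pytest.raises(ValueError):
            rescale_effect(p=0.0, sign="+", n=1000, f=0.3)

    @settings(max_examples=60, deadline=None)
    @given(
        beta=st.floats(0.01, 1.0),
        n=st.integers(2_000, 200_000),
        f=st.floats(0.01, 0.5),
    )
    def test_round_trip_recovers_simulated_beta(self, beta, n, f):
        """p implied by (beta, se) feeds back through rescaling to beta."""
        se = 1.0 / np.sqrt(2 * n * f * (1 - f))
        z = beta / se
        log10_p = (np.log(2.0) + stats.norm.logsf(z)) / np.log(10)
        se2, beta2 = rescale_effect(p=None, log10_p=log10_p, sign="+", n=n, f=f)
        assert beta2 == pytest.approx(beta, rel=1e-6)


class TestPower:
    def test_zero_beta_gives_floor_power(self):
        assert compute_power(0.0, 50_000, 0.3) == pytest.approx(1e-8)

    def test_monotone_in_abs_beta_and_sign_invariant(self):
        grid = [0.05, 0.1, 0.2, 0.4]
        vals = [compute_power(b, 50_000, 0.3) for b in grid]
        assert all(a < b for a, b in zip(vals, vals[1:]))
        assert compute_power(-0.2, 50_000, 0.3) == compute_power(0.2, 50_000, 0.3)

    def test_monte_carlo_oracle(self, rng):
        """Non-central chi-square tail reproduced by direct simulation."""
        beta, n_eff, maf = 0.3, 50_000, 0.02
        ncp = beta**2 * n_eff * 2 * maf * (1 - maf) / 11.0
        q = stats.chi2.isf(1e-8, df=1)
        draws = (rng.standard_normal(1_000_000) + np.sqrt(ncp)) ** 2
        mc = (draws > q).mean()
        se = np.sqrt(mc * (1 - mc) / 1_000_000)
        assert abs(compute_power(beta, n_eff, maf) - mc) < 3 * se + 1e-6

    def test_effective_sample_size_convention(self):
        assert effective_sample_size(1000) == 1000
        assert effective_sample_size(1000, 500) == pytest.approx(1000)
        assert effective_sample_size(10_000, 1_000) == pytest.approx(
            4 / (1 / 1_000 + 1 / 9_000)
        )

    def test_invalid_inputs_fail(self):
        with pytest.raises(ValueError):
            compute_power(0.1, -5, 0.3)
        with pytest.raises(ValueError):
            compute_power(0.1, 100, 0.7)


class TestConsequence:
    @pytest.mark.parametrize(
        "cats,expect",
        [({"enhancer", "PAV"}, "PAV"), ({"intergenic"}, "intergenic"),
         ({"promoter", "enhancer"}, "promoter"),
         ({"intragenic", "intergenic", "enhancer"}, "enhancer")],
    )
    def test_most_severe_selected(self, cats, expect):
        assert resolve_most_severe(cats) == expect

    def test_empty_and_unknown_rejected(self):
        with pytest.raises(ValueError):
            resolve_most_severe([])
        with pytest.raises(ValueError):
            resolve_most_severe(["missense"])


def _cs_row(cs_id, variant="v1", trait="EFO:1", pip=0.9, beta=0.5, qual=True, repl=True):
    return {"cs_id": cs_id, "lead_variant": variant, "trait_id": trait,
            "lead_pip": pip, "qualified": qual, "replicated": repl, "beta_resc": beta}


class TestRepresentativeFilter:
    def test_largest_abs_effect_kept_per_variant_trait(self):
        df = pd.DataFrame([_cs_row("a", beta=0.2), _cs_row("b", beta=0.5)])
        out = filter_lead_variants_for_consequence_analysis(df)
        assert list(out["cs_id"]) == ["b"]

    def test_boundary_pip_dropped(self):
        df = pd.DataFrame([_cs_row("a", pip=0.49)])
        assert filter_lead_variants_for_consequence_analysis(df).empty

    def test_all_pass_identity(self):
        df = pd.DataFrame([_cs_row("a", variant="v1"), _cs_row("b", variant="v2")])
        out = filter_lead_variants_for_consequence_analysis(df)
        assert sorted(out["cs_id"]) == ["a", "b"]


class TestReplication:
    def _table(self, rows):
        return pd.DataFrame(rows)

    def test_two_cohorts_same_trait_replicates(self):
        studies = {
            "S1": _study(study_id="S1", cohort="UKB", publication="P1"),
            "S2": _study(study_id="S2", cohort="FINNGEN", publication="P2"),
        }
        tab = self._table([
            {"cs_id": "a", "study_id": "S1", "study_type": "disease",
             "lead_variant": "v1", "trait_id": "EFO:1"},
            {"cs_id": "b", "study_id": "S2", "study_type": "disease",
             "lead_variant": "v1", "trait_id": "EFO:1"},
        ])
        assert flag_replication(tab, studies).all()

    def test_same_context_twice_not_replicated(self):
        studies = {
            "S1": _study(study_id="S1", cohort="UKB", publication="P1"),
            "S2": _study(study_id="S2", cohort="UKB", publication="P1"),
        }
        tab = self._table([
            {"cs_id": "a", "study_id": "S1", "study_type": "disease",
             "lead_variant": "v1", "trait_id": "EFO:1"},
            {"cs_id": "b", "study_id": "S2", "study_type": "disease",
             "lead_variant": "v1", "trait_id": "EFO:1"},
        ])
        assert not flag_replication(tab, studies).any()

    def test_molqtl_lead_gene_twice_anywhere_replicates(self):
        studies = {
            "Q1": _study(study_id="Q1", study_type="eqtl", n_cases=None),
            "Q2": _study(study_id="Q2", study_type="eqtl", n_cases=None),
        }
        tab = self._table([
            {"cs_id": "a", "study_id": "Q1", "study_type": "eqtl",
             "lead_variant": "v1", "trait_id": "x", "gene_id": "G1"},
            {"cs_id": "b", "study_id": "Q2", "study_type": "eqtl",
             "lead_variant": "v1", "trait_id": "y", "gene_id": "G1"},
        ])
        assert flag_replication(tab, studies).all()


class TestQualification:
    def test_study_rules_and_boundaries(self):
        studies = {
            "exact": _study(study_id="exact", n=1000, n_cases=500),
            "lowprev": _study(study_id="lowprev", n=50_000, n_cases=40),
            "ok": _study(study_id="ok", n=20_000, n_cases=4_000),
            "prot": _study(study_id="prot", study_type="measurement", n_cases=None,
                           trait_category="protein_measurement"),
            "meas": _study(study_id="meas", study_type="measurement", n_cases=None),
        }
        q = qualify_studies(studies)
        assert not q["exact"]          # n must exceed 1000 strictly
        assert not q["lowprev"]        # prevalence 0.0008 < 0.1%
        assert q["ok"]
        assert not q["prot"]
        assert q["meas"]

    def _cs_table(self, **kw):
        base = {"cs_id": "a", "study_id": "S", "maf": 0.3, "beta_resc": 0.1,
                "n": 20_000, "replicated": False}
        base.update(kw)
        return pd.DataFrame([base])

    def test_rare_variant_without_evidence_rejected(self):
        tab = self._cs_table(maf=0.005)
        assert not qualify_credible_sets(tab, {"S": True}).iloc[0]

    def test_beta_boundary_strict(self):
        tab = self._cs_table(beta_resc=3.0)
        assert not qualify_credible_sets(tab, {"S": True}).iloc[0]

    def test_common_all_pass(self):
        tab = self._cs_table()
        assert qualify_credible_sets(tab, {"S": True}).iloc[0]

    def test_monotone_in_added_evidence(self):
        tab = self._cs_table(maf=0.005)
        base = qualify_credible_sets(tab, {"S": True}).iloc[0]
        with_pav = qualify_credible_sets(
            tab, {"S": True}, has_pav=pd.Series([True])
        ).iloc[0]
        with_repl = qualify_credible_sets(
            tab.assign(replicated=True), {"S": True}
        ).iloc[0]
        assert not base and with_pav and with_repl


class TestTherapeuticArea:
    EDGES = {
        "ovarian cancer": ["cell proliferation disorder",
                           "reproductive system or breast disease"],
        "orphan trait": [],
        "height": ["measurement"],
    }

    def test_oncology_priority(self):
        assert assign_therapeutic_area("ovarian cancer", self.EDGES) == \
            "cell proliferation disorder"

    def test_orphan_falls_back_to_other(self):
        assert assign_therapeutic_area("orphan trait", self.EDGES) == "other"
        assert assign_therapeutic_area("height", self.EDGES) == "other"

    def test_ta_root_maps_to_itself(self):
        assert assign_therapeutic_area("eye disease", self.EDGES) == "eye disease"


class TestCredibleSetInvariants:
    def test_pip_sum_and_lead_validation(self):
        cs = CredibleSet("c", "S", "v1", members=[("v1", 0.6), ("v2", 0.36)])
        cs.validate()
        bad = CredibleSet("c", "S", "v2", members=[("v1", 0.6), ("v2", 0.36)])
        with pytest.raises(ValueError, match="maximal PIP"):
            bad.validate()
        with pytest.raises(ValueError, match="sum"):
            CredibleSet("c", "S", "v1", members=[("v1", 0.5)]).validate()
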