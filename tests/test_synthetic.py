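"""Generator contracts: LD validity, determinism, planted-signal behaviour."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pleiomap._utils import named_rng
from pleiomap.synthetic import (
    SimulationConfig,
    TIPlan,
    beta_for_power,
    default_config,
    gws_power,
    simulate_annotations,
    simulate_cohort,
    simulate_ld_genome,
    simulate_molqtl_cs,
    simulate_study_sumstats,
    simulate_ti_pipeline,
    StudySpec,
    build_truth,
    draw_ti_targets,
    pav_rate_for_maf,
)


class TestLdGenome:
    def test_single_variant_block_has_identity_ld(self):
        cfg = SimulationConfig(seed=1, n_ld_blocks=1, variants_per_block=1)
        g = simulate_ld_genome(cfg)
        assert np.allclose(g.ld[0].to_numpy(), [[1.0]])

    def test_same_seed_reproduces_identical_variant_tables(self):
        cfg = SimulationConfig(seed=42)
        g1, g2 = simulate_ld_genome(cfg), simulate_ld_genome(cfg)
        pd.testing.assert_frame_equal(g1.variants, g2.variants)
        for b in g1.ld:
            pd.testing.assert_frame_equal(g1.ld[b], g2.ld[b])

    def test_ld_blocks_are_psd_with_unit_diagonal(self):
        cfg = SimulationConfig(seed=3, n_ld_blocks=10, variants_per_block=50)
        g = simulate_ld_genome(cfg)
        for b, ldm in g.ld.items():
            r = ldm.to_numpy()
            assert np.allclose(r, r.T)
            assert np.allclose(np.diag(r), 1.0)
            assert np.linalg.eigvalsh(r).min() >= -1e-8

    def test_positions_strictly_increasing_within_chromosome(self):
        g = simulate_ld_genome(SimulationConfig(seed=4))
        for _, grp in g.variants.groupby("chrom"):
            assert (np.diff(grp["pos"].to_numpy()) > 0).all()

    def test_nonpositive_counts_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(seed=0, n_ld_blocks=0).validate()


class TestSumstats:
    def test_null_study_has_no_genome_wide_hits(self):
        cfg = SimulationConfig(seed=9, n_ld_blocks=8, variants_per_block=50)
        g = simulate_ld_genome(cfg)
        st = StudySpec("NULL1", "measurement", "EFO:M1", n=50_000, signals=[])
        ss = simulate_study_sumstats(g, st, cfg)
        # 400 null variants; expected GWS count is ~4e-6
        assert (ss["p_value"] <= 1e-8).sum() == 0

    def test_unknown_signal_variant_fails_naming_the_id(self, small_genome, small_config):
        st = StudySpec("S1", "disease", "EFO:D1", n=10_000, n_cases=2_000,
                       signals=[("9_999_A_C", 0.3)])
        with pytest.raises(KeyError, match="9_999_A_C"):
            simulate_study_sumstats(small_genome, st, small_config)

    def test_planted_high_power_signal_recovered_across_seeds(self):
        hits = 0
        n_seeds = 40
        for seed in range(n_seeds):
            cfg = SimulationConfig(seed=seed, n_ld_blocks=1, variants_per_block=20)
            g = simulate_ld_genome(cfg)
            vid = g.variants.iloc[10]["variant_id"]
            f = float(g.variants.iloc[10]["maf"])
            beta = beta_for_power(0.99, n=30_000, f=f)
            st = StudySpec("S", "measurement", "T", n=30_000, signals=[(vid, beta)])
            ss = simulate_study_sumstats(g, st, cfg)
            p = ss.set_index("variant_id").loc[vid, "p_value"]
            hits += p <= 1e-8
        # planted power 0.99: >= 95% recovery expected
        assert hits >= round(0.95 * n_seeds) - 1

    def test_mean_abs_effect_decreases_with_maf(self, cohort):
        """Rarer genome-wide significant lead variants carry larger effects."""
        vindex = cohort.genome.variants.set_index("variant_id")["maf"]
        rows = []
        for _, r in cohort.truth.signals.iterrows():
            rows.append({"maf": float(vindex[r["causal_variant"]]),
                         "abs_beta": abs(r["beta"])})
        df = pd.DataFrame(rows)
        low = df[df["maf"] <= 0.05]["abs_beta"].mean()
        high = df[df["maf"] > 0.1]["abs_beta"].mean()
        assert low > high


class TestCredibleSets:
    def test_molqtl_cs_pip_sums_and_shared_top_variant(self, cohort):
        planted = cohort.truth.signals[cohort.truth.signals["has_molqtl"]]
        planted_variants = set(planted["causal_variant"])
        seen = 0
        for cs in cohort.molqtl_cs:
            pips = [p for _, p in cs["members"]]
            assert 0.95 <= sum(pips) <= 1 + 1e-9
            assert all(0 <= p <= 1 for p in pips)
            if cs["trait_id"] != "bg":
                assert cs["lead_variant"] in planted_variants
                # lead is the highest-PIP member
                assert cs["members"][0][0] == cs["lead_variant"]
                seen += 1
        assert seen == planted["gene_id"].nunique()

    def test_planted_pair_clpp_exceeds_threshold(self, cohort):
        gwas_by_lead = {}
        for cs in cohort.gwas_cs:
            gwas_by_lead.setdefault(cs["lead_variant"], []).append(dict(cs["members"]))
        for cs in cohort.molqtl_cs:
            if cs["trait_id"] == "bg":
                continue
            for gwas_pips in gwas_by_lead.get(cs["lead_variant"], []):
                clpp = sum(p * gwas_pips.get(v, 0.0) for v, p in cs["members"])
                assert clpp >= 0.01

    def test_random_pair_clpp_negligible(self, cohort, rng):
        mol = [dict(cs["members"]) for cs in cohort.molqtl_cs]
        gwas = [dict(cs["members"]) for cs in cohort.gwas_cs]
        vals = []
        for _ in range(200):
            a = mol[rng.integers(len(mol))]
            b = gwas[rng.integers(len(gwas))]
            vals.append(sum(p * b.get(v, 0.0) for v, p in a.items()))
        assert np.median(vals) < 0.01


class TestAnnotations:
    def test_zero_pav_rate_yields_no_pav_rows(self, small_genome, small_config):
        import dataclasses

        cfg = dataclasses.replace(small_config, pav_rates=((0.5, 0.0),),
                                  pleiotropy_plan=small_config.pleiotropy_plan)
        ann, _, _ = simulate_annotations(small_genome, cfg)
        assert (ann["category"] != "PAV").all()

    def test_pathogenicity_scores_in_unit_interval(self, cohort):
        assert cohort.variant_annotations["pathogenicity"].between(0, 1).all()

    def test_empirical_pav_rates_match_config_within_binomial_ci(self):
        cfg = SimulationConfig(seed=21, n_ld_blocks=20, variants_per_block=60)
        g = simulate_ld_genome(cfg)
        ann, _, _ = simulate_annotations(g, cfg)
        mafs = g.variants.set_index("variant_id")["maf"]
        ann = ann.assign(maf=ann["variant_id"].map(mafs))
        for lo, hi in [(0.0, 0.01), (0.01, 0.05), (0.05, 0.1), (0.1, 0.5)]:
            sub = ann[(ann["maf"] > lo) & (ann["maf"] <= hi)]
            if len(sub) < 30:
                continue
            rate = pav_rate_for_maf((lo + hi) / 2, cfg.pav_rates)
            k = (sub["category"] == "PAV").sum()
            lo_ci, hi_ci = stats.binom.interval(0.999, len(sub), rate)
            assert lo_ci <= k <= hi_ci


class TestTiPipeline:
    def test_null_plan_gives_or_near_one(self, rng):
        plan = TIPlan(n_records=30_000, b_support=0.0)
        ti = simulate_ti_pipeline(draw_ti_targets(plan, rng), plan, rng)
        tab = pd.crosstab(ti["support"], ti["approved"]).to_numpy()
        orr = (tab[1, 1] * tab[0, 0]) / (tab[1, 0] * tab[0, 1])
        assert 0.85 < orr < 1.18

    def test_planted_support_or_recovered(self, rng):
        plan = TIPlan(n_records=30_000)
        ti = simulate_ti_pipeline(draw_ti_targets(plan, rng), plan, rng)
        tab = pd.crosstab(ti["support"], ti["approved"]).to_numpy()
        orr = (tab[1, 1] * tab[0, 0]) / (tab[1, 0] * tab[0, 1])
        assert 3.0 < orr < 4.3

    def test_invalid_transition_probability_rejected(self, rng):
        plan = TIPlan(q12=1.4)
        with pytest.raises(ValueError, match="q12"):
            plan.validate()

    def test_missing_column_fails(self, rng):
        plan = TIPlan()
        with pytest.raises(ValueError, match="unique_diseases"):
            simulate_ti_pipeline(pd.DataFrame({"target_id": ["G1"], "support": [1]}),
                                 plan, rng)


class TestDeterminismAndClosure:
    def test_identical_config_reproduces_cohort(self, small_config):
        c1 = simulate_cohort(small_config)
        c2 = simulate_cohort(small_config)
        pd.testing.assert_frame_equal(c1.genome.variants, c2.genome.variants)
        pd.testing.assert_frame_equal(c1.truth.signals, c2.truth.signals)
        pd.testing.assert_frame_equal(c1.ti_records, c2.ti_records)
        sid = c1.studies[0].study_id
        pd.testing.assert_frame_equal(c1.sumstats[sid], c2.sumstats[sid])

    def test_truth_table_closure(self, cohort):
        cohort.truth.check_closure(cohort.genome)
        for g, ds in cohort.truth.gene_diseases.items():
            assert cohort.truth.true_gps(g) == len(ds) >= 1

    def test_power_formula_round_trip(self):
        beta = beta_for_power(0.9, n=50_000, f=0.3)
        se = 1.0 / np.sqrt(2 * 50_000 * 0.3 * 0.7)
        assert gws_power((beta / se) ** 2) == pytest.approx(0.9, rel=1e-6)
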