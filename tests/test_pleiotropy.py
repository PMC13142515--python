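"""Cluster construction, pleiotropy counts, count models, set enrichment."""

import numpy as np
import pandas as pd
import pytest

from pleiomap.pleiotropy import (
    beta_concordance,
    cluster_credible_sets,
    compute_gps,
    compute_vps,
    fit_count_model,
    gene_set_enrichment,
    score_tissue_specificity,
)


def _cs_table(rows):
    df = pd.DataFrame(rows)
    if "ta" not in df.columns:
        df["ta"] = "TA1"
    return df


def reachability_oracle(cs_table, coloc_pairs):
    """Independent partition: BFS over coloc + shared-lead edges, seeded in
    significance order."""
    edges = {}
    ids = list(cs_table["cs_id"])
    lead = dict(zip(cs_table["cs_id"], cs_table["lead_variant"]))
    for a, b in coloc_pairs:
        edges.setdefault(a, set()).add(b)
        edges.setdefault(b, set()).add(a)
    for i in ids:
        for j in ids:
            if i != j and lead[i] == lead[j]:
                edges.setdefault(i, set()).add(j)
    order = cs_table.sort_values(["lead_p", "cs_id"])["cs_id"].tolist()
    seen, parts = set(), []
    for s in order:
        if s in seen:
            continue
        comp, frontier = {s}, [s]
        while frontier:
            nxt = []
            for x in frontier:
                for y in edges.get(x, ()):  # undirected reachability
                    if y not in comp:
                        comp.add(y)
                        nxt.append(y)
            frontier = nxt
        seen |= comp
        parts.append(frozenset(comp))
    return set(parts)


class TestClustering:
    def test_no_coloc_gives_singletons(self):
        tab = _cs_table([
            {"cs_id": f"c{i}", "lead_variant": f"v{i}", "lead_p": 1e-9,
             "trait_id": f"D{i}"} for i in range(4)
        ])
        clusters = cluster_credible_sets(tab, set())
        assert len(clusters) == 4
        assert all(len(c.member_cs_ids) == 1 for c in clusters)

    def test_expansion_via_shared_lead(self):
        tab = _cs_table([
            {"cs_id": "A", "lead_variant": "v1", "lead_p": 1e-12, "trait_id": "D1"},
            {"cs_id": "B", "lead_variant": "v2", "lead_p": 1e-10, "trait_id": "D2"},
            {"cs_id": "C", "lead_variant": "v2", "lead_p": 1e-9, "trait_id": "D3"},
        ])
        clusters = cluster_credible_sets(tab, {("A", "B")})
        assert len(clusters) == 1
        assert set(clusters[0].member_cs_ids) == {"A", "B", "C"}

    def test_partition_property_and_oracle_agreement(self, rng):
        for _ in range(60):
            n = int(rng.integers(2, 12))
            tab = _cs_table([
                {"cs_id": f"c{i}", "lead_variant": f"v{rng.integers(0, max(2, n // 2))}",
                 "lead_p": float(10.0 ** -rng.uniform(8, 20)), "trait_id": f"D{i % 4}"}
                for i in range(n)
            ])
            pairs = set()
            for _ in range(int(rng.integers(0, n))):
                i, j = rng.choice(n, size=2, replace=False)
                pairs.add((f"c{i}", f"c{j}"))
            clusters = cluster_credible_sets(tab, pairs)
            got = {frozenset(c.member_cs_ids) for c in clusters}
            assert got == reachability_oracle(tab, pairs)
            all_members = [m for c in clusters for m in c.member_cs_ids]
            assert sorted(all_members) == sorted(tab["cs_id"])


class TestScores:
    def test_vps_unique_diseases(self):
        tab = _cs_table([
            {"cs_id": "A", "lead_variant": "v1", "lead_p": 1e-9, "trait_id": "D1"},
            {"cs_id": "B", "lead_variant": "v1", "lead_p": 1e-9, "trait_id": "D2"},
            {"cs_id": "C", "lead_variant": "v1", "lead_p": 1e-8, "trait_id": "D1"},
        ])
        (cluster,) = cluster_credible_sets(tab, set())
        assert compute_vps(cluster) == (2, 1)

    def test_multi_lead_union(self):
        tab = _cs_table([
            {"cs_id": "A", "lead_variant": "v1", "lead_p": 1e-9, "trait_id": "D1"},
            {"cs_id": "B", "lead_variant": "v2", "lead_p": 1e-9, "trait_id": "D2"},
            {"cs_id": "C", "lead_variant": "v2", "lead_p": 1e-8, "trait_id": "D3"},
        ])
        (cluster,) = cluster_credible_sets(tab, {("A", "B")})
        assert cluster.vps == 3

    @pytest.mark.parametrize("signs,expect", [
        (["+", "+", "-"], 2 / 3), (["+"], 1.0), (["+", "-"], 0.5),
        ([1, 1, 1, -1], 0.75),
    ])
    def test_beta_concordance(self, signs, expect):
        assert beta_concordance(signs) == pytest.approx(expect)

    def test_concordance_requires_usable_signs(self):
        with pytest.raises(ValueError):
            beta_concordance(["+", "unknown"])
        with pytest.raises(ValueError):
            beta_concordance([])

    def test_gps_union_over_variants(self):
        prio = pd.DataFrame({
            "gene_id": ["G1", "G1", "G1", "G2"],
            "trait_id": ["A", "B", "C", "A"],
            "ta": ["t1", "t1", "t2", "t1"],
        })
        gps = compute_gps(prio).set_index("gene_id")
        assert gps.loc["G1", "gps"] == 3
        assert gps.loc["G1", "ta_count"] == 2
        assert gps.loc["G2", "gps"] == 1

    def test_planted_gps_recovery(self, cohort):
        for gene, diseases in cohort.truth.gene_diseases.items():
            assert cohort.truth.true_gps(gene) == len(diseases)


class TestTissueSpecificity:
    def test_single_dominant_tissue_enriched(self):
        x = pd.Series([10.0] + [1.0] * 9)
        assert score_tissue_specificity(x) == (1.0, 1)

    def test_uniform_low_specificity(self):
        assert score_tissue_specificity(pd.Series([2.0] * 8)) == (-1.0, 0)

    def test_exact_fourfold_boundary_inclusive(self):
        x = pd.Series([4.0] + [1.0] * 5)
        assert score_tissue_specificity(x) == (1.0, 1)

    def test_group_enriched(self):
        x = pd.Series([8.0, 8.0, 1.0, 1.0, 1.0, 1.0])
        assert score_tissue_specificity(x) == (0.75, 0)

    def test_enhanced(self):
        x = pd.Series([5.0, 2.0, 1.0, 1.0, 1.0, 1.0])
        score, binary = score_tissue_specificity(x)
        assert score == 0.5 and binary == 0

    def test_undetected_excluded(self):
        assert score_tissue_specificity(pd.Series([0.0, 0.0])) is None


class TestCountModel:
    def test_null_covariates_explain_nothing(self, rng):
        y = rng.poisson(3, 2000) + 1
        cov = pd.DataFrame({"a": rng.uniform(0, 1, 2000), "b": rng.uniform(0, 1, 2000)})
        fit = fit_count_model(y, cov)
        assert fit["pearson_r2"] < 0.01
        assert np.all(np.abs(fit["coefficients"]["coef"]) < 0.2)

    def test_planted_coefficient_recovered_within_two_se(self, rng):
        n = 5000
        x = rng.uniform(0, 1, n)
        beta = 1.5
        y = rng.poisson(np.exp(0.3 + beta * x))
        fit = fit_count_model(y, pd.DataFrame({"power": x, "noise": rng.uniform(0, 1, n)}))
        row = fit["coefficients"].set_index("covariate").loc["power"]
        assert abs(row["coef"] - beta) < 2 * row["se"]
        assert fit["r2_deltas"]["power"] > fit["r2_deltas"]["noise"]

    def test_constant_covariate_dropped_with_warning(self, rng):
        y = rng.poisson(2, 500) + 1
        cov = pd.DataFrame({"c": np.ones(500), "x": rng.uniform(0, 1, 500)})
        with pytest.warns(UserWarning, match="constant"):
            fit = fit_count_model(y, cov)
        assert fit["dropped"] == ["c"]

    def test_non_integer_counts_rejected(self, rng):
        with pytest.raises(ValueError):
            fit_count_model(np.array([0.5, 1.2]), pd.DataFrame({"x": [0.1, 0.9]}))


class TestGeneSetEnrichment:
    def _table(self, n, rng):
        gps = np.maximum(1, np.round(np.exp(rng.normal(0.8, 0.9, n)))).astype(int)
        return pd.DataFrame({"gene_id": [f"G{i}" for i in range(n)], "gps": gps})

    def test_null_set_no_signal(self, rng):
        tab = self._table(3000, rng)
        sets = {"null": set(rng.choice(tab["gene_id"], 300, replace=False))}
        res = gene_set_enrichment(tab, sets)
        assert abs(res.iloc[0]["log_odds"]) < 3 * res.iloc[0]["se"] + 0.1

    def test_planted_log_odds_recovered(self, rng):
        tab = self._table(8000, rng)
        x = np.log2(tab["gps"].to_numpy())
        eta = -2.0 + np.log(2) * x
        member = rng.random(8000) < 1 / (1 + np.exp(-eta))
        sets = {"planted": set(tab.loc[member, "gene_id"])}
        res = gene_set_enrichment(tab, sets).iloc[0]
        assert abs(res["log_odds"] - np.log(2)) < 2 * res["se"]

    def test_zero_overlap_skipped(self, rng):
        tab = self._table(100, rng)
        with pytest.warns(UserWarning, match="no overlap"):
            res = gene_set_enrichment(tab, {"empty": {"ZZZ"}})
        assert res.empty
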