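"""End-to-end orchestration of the synthetic post-GWAS pipeline.

Stage order: simulate -> harmonise -> finemap -> coloc -> l2g -> pleiotropy
-> translate.  Every stage reads its inputs from, and writes its outputs to,
a run directory, so any stage can be re-run from prior outputs.  A manifest
records the config hash, seeds and per-stage output digests; identical
configs reproduce identical output digests.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import coloc as coloc_mod
from . import harmonise as hz
from . import io as pio
from . import l2g as l2g_mod
from . import pleiotropy as pt
from . import translation as tr
from .finemap import apply_lead_p_threshold, clump_by_distance, pics_finemap
from .synthetic import Genome, SimulationConfig, simulate_cohort

STAGES = ("simulate", "harmonise", "finemap", "coloc", "l2g", "pleiotropy", "translate")
__version__ = "0.1.0"


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _require(out_dir: Path, stage: str, *names: str) -> list[Path]:
    paths = []
    for name in names:
        p = out_dir / name
        if not p.exists():
            raise FileNotFoundError(
                f"stage '{stage}' requires missing upstream output '{name}'"
            )
        paths.append(p)
    return paths


def load_genome(out_dir: Path) -> Genome:
    variants = pd.read_csv(out_dir / "genome_variants.tsv", sep="\t",
                           dtype={"chrom": str})
    genes = pd.read_csv(out_dir / "genes.tsv", sep="\t", dtype={"chrom": str})
    ld = {}
    for b in sorted(variants["block"].unique()):
        ld[int(b)] = pio.read_ld(out_dir / f"ld_block_{int(b)}.tsv")
    return Genome(variants, ld, genes)


# --------------------------------------------------------------------------- #
# stages                                                                      #
# --------------------------------------------------------------------------- #


def stage_simulate(config: SimulationConfig, out_dir: Path) -> list[Path]:
    cohort = simulate_cohort(config)
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "sumstats").mkdir(exist_ok=True)
    written = []

    def w(path: Path):
        written.append(path)
        return path

    config.to_yaml(w(out_dir / "config.yaml"))
    cohort.genome.variants.to_csv(w(out_dir / "genome_variants.tsv"), sep="\t", index=False)
    cohort.genome.genes.to_csv(w(out_dir / "genes.tsv"), sep="\t", index=False)
    for b, ldm in cohort.genome.ld.items():
        pio.write_ld(ldm, w(out_dir / f"ld_block_{b}.tsv"))
    studies_df = pd.DataFrame(
        [{"study_id": s.study_id, "study_type": s.study_type, "trait_id": s.trait_id,
          "n": s.n, "n_cases": s.n_cases, "cohort": s.cohort,
          "publication": s.publication, "ancestry": s.ancestry, "year": s.year}
         for s in cohort.studies]
    )
    studies_df.to_csv(w(out_dir / "studies.tsv"), sep="\t", index=False)
    for sid, df in cohort.sumstats.items():
        pio.write_sumstats(df, w(out_dir / "sumstats" / f"{sid}.tsv"))
    pio.write_credible_sets(
        [_dict_to_cs(d) for d in cohort.gwas_cs], w(out_dir / "gwas_cs.jsonl")
    )
    mol = []
    for d in cohort.molqtl_cs:
        cs = _dict_to_cs(d)
        cs.trait_id = d["trait_id"]
        mol.append(cs)
    pio.write_credible_sets(mol, w(out_dir / "molqtl_cs.jsonl"))
    molqtl_genes = pd.DataFrame(
        [{"cs_id": d["cs_id"], "gene_id": d["gene_id"], "qtl_type": d["study_type"]}
         for d in cohort.molqtl_cs]
    )
    molqtl_genes.to_csv(w(out_dir / "molqtl_genes.tsv"), sep="\t", index=False)
    cohort.variant_annotations.to_csv(w(out_dir / "variant_annotations.tsv"),
                                      sep="\t", index=False)
    cohort.gene_covariates.to_csv(w(out_dir / "gene_covariates.tsv"), sep="\t", index=False)
    cohort.expression.to_csv(w(out_dir / "expression.tsv"), sep="\t")
    cohort.ti_records.to_csv(w(out_dir / "ti_records.tsv"), sep="\t", index=False)
    cohort.truth.signals.to_csv(w(out_dir / "truth_signals.tsv"), sep="\t", index=False)
    # disease -> therapeutic-area ontology edges for TA assignment
    edges = {
        row["trait_id"]: [row["ta"]]
        for _, row in cohort.truth.signals.drop_duplicates("trait_id").iterrows()
    }
    pio.write_ontology_edges(edges, w(out_dir / "ontology.tsv"))
    return written


def _dict_to_cs(d: dict) -> hz.CredibleSet:
    return hz.CredibleSet(
        cs_id=d["cs_id"], study_id=d["study_id"], lead_variant=d["lead_variant"],
        members=[(v, float(p)) for v, p in d["members"]], method=d["method"],
        lead_p=float(d["lead_p"]), beta_sign=d["beta_sign"],
        region=tuple(d["region"]), study_type=d["study_type"],
        trait_id=d.get("trait_id", ""), lead_beta=float(d.get("lead_beta", np.nan)),
    )


def _load_studies(out_dir: Path) -> dict[str, hz.StudyRecord]:
    df = pd.read_csv(out_dir / "studies.tsv", sep="\t")
    out = {}
    for _, r in df.iterrows():
        out[r["study_id"]] = hz.StudyRecord(
            study_id=r["study_id"], study_type=r["study_type"], trait_id=r["trait_id"],
            n=int(r["n"]), n_cases=None if pd.isna(r["n_cases"]) else int(r["n_cases"]),
            ancestry_composition={str(r.get("ancestry", "NFE")): 1.0},
            year=int(r["year"]), cohort=str(r["cohort"]), publication=str(r["publication"]),
        )
    return out


def stage_harmonise(out_dir: Path) -> list[Path]:
    _require(out_dir, "harmonise", "studies.tsv", "ontology.tsv")
    studies = _load_studies(out_dir)
    edges = pio.read_ontology_edges(out_dir / "ontology.tsv")
    tas = sorted({t for ps in edges.values() for t in ps})
    hierarchy = tuple(tas) + ("other",)
    qualified = hz.qualify_studies(studies)
    rows = []
    for sid, st in studies.items():
        st.validate()
        rows.append(
            {"study_id": sid, "study_type": st.study_type, "trait_id": st.trait_id,
             "n": st.n, "n_cases": st.n_cases, "qualified": qualified[sid],
             "ta": hz.assign_therapeutic_area(st.trait_id, edges, hierarchy)}
        )
    out = pd.DataFrame(rows)
    path = out_dir / "studies_harmonised.tsv"
    out.to_csv(path, sep="\t", index=False)
    return [path]


def stage_finemap(out_dir: Path) -> list[Path]:
    _require(out_dir, "finemap", "studies.tsv", "genome_variants.tsv")
    genome = load_genome(out_dir)
    studies = _load_studies(out_dir)
    vblock = genome.variants.set_index("variant_id")["block"]
    cs_all = []
    for sid, st in sorted(studies.items()):
        ss_path = out_dir / "sumstats" / f"{sid}.tsv"
        if not ss_path.exists():
            raise FileNotFoundError(f"stage 'finemap' requires missing sumstats for {sid}")
        ss = pio.read_sumstats(ss_path)
        for locus in clump_by_distance(ss):
            block = int(vblock[locus.top_variant])
            ld_row = genome.ld[block][locus.top_variant]
            cs = pics_finemap(
                locus, ld_row, cs_id=f"{sid}:{locus.top_variant}", study_id=sid
            )
            cs.study_type = st.study_type
            cs.trait_id = st.trait_id
            cs_all.append(cs)
    cs_all = apply_lead_p_threshold(cs_all, "gwas")
    path = out_dir / "pics_cs.jsonl"
    pio.write_credible_sets(cs_all, path)
    return [path]


def stage_coloc(out_dir: Path) -> list[Path]:
    _require(out_dir, "coloc", "pics_cs.jsonl", "molqtl_cs.jsonl",
             "variant_annotations.tsv", "studies_harmonised.tsv")
    gwas_cs = pio.read_credible_sets(out_dir / "pics_cs.jsonl")
    mol_cs = pio.read_credible_sets(out_dir / "molqtl_cs.jsonl")
    for cs in mol_cs:
        if cs.study_type == "disease":
            cs.study_type = "eqtl"
    coloc_results = coloc_mod.colocalise_all(gwas_cs + mol_cs)
    coloc_df = coloc_mod.coloc_results_frame(coloc_results)
    coloc_path = out_dir / "coloc.tsv"
    coloc_df.to_csv(coloc_path, sep="\t", index=False)

    # annotate + qualify the GWAS credible sets
    studies = _load_studies(out_dir)
    stable = pd.read_csv(out_dir / "studies_harmonised.tsv", sep="\t")
    ta_of_trait = dict(zip(stable["trait_id"], stable["ta"]))
    study_qualified = dict(zip(stable["study_id"], stable["qualified"]))
    ann = pd.read_csv(out_dir / "variant_annotations.tsv", sep="\t")
    mol_ids = {cs.cs_id for cs in mol_cs}
    sig_pairs = set()
    for _, r in coloc_df[coloc_df["significant"]].iterrows():
        sig_pairs.add((r["left_cs_id"], r["right_cs_id"]))
    has_mol_coloc = {
        cs.cs_id: any(
            (a == cs.cs_id and b in mol_ids) or (b == cs.cs_id and a in mol_ids)
            for a, b in sig_pairs
        )
        for cs in gwas_cs
    }
    pav_variants = set(ann.loc[ann["category"] == "PAV", "variant_id"])
    rows = []
    for cs in gwas_cs:
        st = studies[cs.study_id]
        maf = hz.annotate_major_ancestry_maf(st, cs.lead_variant, ann)
        if maf is None:
            continue  # failed annotation: excluded downstream
        trait_type = "binary" if st.study_type == "disease" else "quantitative"
        K = (st.n_cases / st.n) if trait_type == "binary" else None
        se_hat, beta_resc = hz.rescale_effect(
            p=max(cs.lead_p, 1e-300), sign=cs.beta_sign, n=st.n, f=maf, K=K,
            trait_type=trait_type,
        )
        rows.append(
            {"cs_id": cs.cs_id, "study_id": cs.study_id, "study_type": cs.study_type,
             "trait_id": cs.trait_id, "ta": ta_of_trait.get(cs.trait_id, "other"),
             "lead_variant": cs.lead_variant, "lead_p": cs.lead_p,
             "lead_pip": cs.pip_of(cs.lead_variant), "maf": maf, "n": st.n,
             "se_hat": se_hat, "beta_resc": beta_resc,
             "has_pav": any(v in pav_variants for v, _ in cs.members),
             "has_mol_coloc": has_mol_coloc[cs.cs_id]}
        )
    cs_table = pd.DataFrame(rows)
    cs_table["replicated"] = hz.flag_replication(cs_table, studies)
    cs_table["qualified"] = hz.qualify_credible_sets(
        cs_table, study_qualified,
        has_significant_coloc=cs_table["has_mol_coloc"],
        has_pav=cs_table["has_pav"],
    )
    table_path = out_dir / "cs_table.tsv"
    cs_table.to_csv(table_path, sep="\t", index=False)
    return [coloc_path, table_path]


def stage_l2g(out_dir: Path, seed: int) -> list[Path]:
    _require(out_dir, "l2g", "pics_cs.jsonl", "cs_table.tsv", "coloc.tsv",
             "molqtl_genes.tsv", "truth_signals.tsv")
    gwas_cs = pio.read_credible_sets(out_dir / "pics_cs.jsonl")
    cs_table = pd.read_csv(out_dir / "cs_table.tsv", sep="\t")
    qualified_ids = set(cs_table.loc[cs_table["qualified"], "cs_id"])
    gwas_cs = [cs for cs in gwas_cs if cs.cs_id in qualified_ids]
    genome = load_genome(out_dir)
    coloc_df = pd.read_csv(out_dir / "coloc.tsv", sep="\t")
    molqtl_genes = pd.read_csv(out_dir / "molqtl_genes.tsv", sep="\t")
    mol_map = {
        r["cs_id"]: (r["gene_id"], r["qtl_type"]) for _, r in molqtl_genes.iterrows()
    }
    ann = pd.read_csv(out_dir / "variant_annotations.tsv", sep="\t")
    vpos = genome.variants.rename(columns={"pos": "pos"})[["variant_id", "chrom", "pos"]]
    fm = l2g_mod.build_feature_matrix(
        gwas_cs, genome.genes, vpos, coloc_df=coloc_df, molqtl_gene_of_cs=mol_map,
        vep_scores=ann.rename(columns={"pathogenicity": "pathogenicity"})[
            ["variant_id", "gene_id", "pathogenicity"]
        ],
    )
    fm_path = out_dir / "feature_matrix.tsv"
    fm.to_csv(fm_path, sep="\t", index=False)
    truth = pd.read_csv(out_dir / "truth_signals.tsv", sep="\t")
    gold = [
        l2g_mod.GoldStandardPair(gene_id=r["gene_id"], trait_id=r["trait_id"])
        for _, r in truth.iterrows()
    ]
    cs_traits = {cs.cs_id: cs.trait_id for cs in gwas_cs}
    labelled = l2g_mod.assemble_training_set(gold, fm, cs_traits, seed=seed)
    scored_path = out_dir / "l2g_scores.tsv"
    sel_path = out_dir / "l2g_selections.tsv"
    metrics_path = out_dir / "l2g_metrics.json"
    if labelled.empty or (labelled["label"] == "positive").sum() < 2:
        pd.DataFrame().to_csv(scored_path, sep="\t", index=False)
        pd.DataFrame(columns=["cs_id", "gene_id", "l2g_score"]).to_csv(
            sel_path, sep="\t", index=False
        )
        metrics = {}
    else:
        scored, metrics, _ = l2g_mod.train_and_score(labelled, seed=seed)
        scored.to_csv(scored_path, sep="\t", index=False)
        sel = l2g_mod.select_effector_genes(scored)
        sel.to_csv(sel_path, sep="\t", index=False)
    with open(metrics_path, "w") as fh:
        json.dump(metrics, fh, indent=2, sort_keys=True)
    return [fm_path, scored_path, sel_path, metrics_path]


def stage_pleiotropy(out_dir: Path) -> list[Path]:
    _require(out_dir, "pleiotropy", "cs_table.tsv", "coloc.tsv", "l2g_selections.tsv",
             "gene_covariates.tsv", "expression.tsv")
    cs_table = pd.read_csv(out_dir / "cs_table.tsv", sep="\t")
    disease = cs_table[(cs_table["study_type"] == "disease") & cs_table["qualified"]]
    coloc_df = pd.read_csv(out_dir / "coloc.tsv", sep="\t")
    ids = set(disease["cs_id"])
    pairs = {
        (r["left_cs_id"], r["right_cs_id"])
        for _, r in coloc_df[coloc_df["significant"]].iterrows()
        if r["left_cs_id"] in ids and r["right_cs_id"] in ids
    }
    clusters = pt.cluster_credible_sets(disease, pairs)
    cl_df = pd.DataFrame(
        [{"cluster_id": c.cluster_id, "n_cs": len(c.member_cs_ids),
          "n_leads": len(c.lead_variants), "vps": c.vps, "ta_count": c.ta_count,
          "lead_variants": ";".join(sorted(c.lead_variants))}
         for c in clusters]
    )
    cl_path = out_dir / "clusters.tsv"
    cl_df.to_csv(cl_path, sep="\t", index=False)

    sel = pd.read_csv(out_dir / "l2g_selections.tsv", sep="\t")
    prio = sel.merge(disease[["cs_id", "trait_id", "ta"]], on="cs_id", how="inner")
    gps = pt.compute_gps(prio) if not prio.empty else pd.DataFrame(
        columns=["gene_id", "gps", "ta_count"]
    )
    expr = pd.read_csv(out_dir / "expression.tsv", sep="\t", index_col=0)
    tspec = []
    for g in gps["gene_id"]:
        res = pt.score_tissue_specificity(expr.loc[g]) if g in expr.index else None
        tspec.append(res if res else (np.nan, 0))
    if len(gps):
        gps["tissue_specificity"] = [t[0] for t in tspec]
        gps["tissue_specific_binary"] = [t[1] for t in tspec]
    gps_path = out_dir / "gene_scores.tsv"
    gps.to_csv(gps_path, sep="\t", index=False)

    model_path = out_dir / "count_model.json"
    model_out = {}
    if len(gps) >= 10:
        cov = pd.read_csv(out_dir / "gene_covariates.tsv", sep="\t")
        dat = gps.merge(cov, on="gene_id", how="inner")
        try:
            fit = pt.fit_count_model(
                dat["gps"].astype(int),
                dat[["lof_constraint", "missense_constraint", "pathway_count",
                     "gene_length"]],
            )
            model_out = {
                "family": fit["family"], "pearson_r2": fit["pearson_r2"],
                "coefficients": fit["coefficients"].to_dict("records"),
                "r2_deltas": fit["r2_deltas"],
            }
        except ValueError:
            model_out = {"skipped": "insufficient variation"}
    with open(model_path, "w") as fh:
        json.dump(model_out, fh, indent=2, sort_keys=True)
    return [cl_path, gps_path, model_path]


def stage_translate(out_dir: Path, seed: int) -> list[Path]:
    _require(out_dir, "translate", "ti_records.tsv", "gene_scores.tsv",
             "l2g_selections.tsv", "cs_table.tsv", "ontology.tsv",
             "variant_annotations.tsv")
    ti = pd.read_csv(out_dir / "ti_records.tsv", sep="\t")
    gps = pd.read_csv(out_dir / "gene_scores.tsv", sep="\t")
    sel = pd.read_csv(out_dir / "l2g_selections.tsv", sep="\t")
    cs_table = pd.read_csv(out_dir / "cs_table.tsv", sep="\t")
    ann = pd.read_csv(out_dir / "variant_annotations.tsv", sep="\t")
    edges = pio.read_ontology_edges(out_dir / "ontology.tsv")
    pav_variants = set(ann.loc[ann["category"] == "PAV", "variant_id"])
    evidence = sel.merge(
        cs_table[cs_table["study_type"] == "disease"][
            ["cs_id", "trait_id", "lead_variant", "maf", "beta_resc"]
        ],
        on="cs_id", how="inner",
    )
    out_paths = []
    enr_path = out_dir / "enrichment.tsv"
    model_path = out_dir / "model_comparison.json"
    trans_path = out_dir / "transitions.tsv"
    if evidence.empty:
        pd.DataFrame().to_csv(enr_path, sep="\t", index=False)
        with open(model_path, "w") as fh:
            json.dump({"skipped": "no evidence"}, fh)
        pd.DataFrame().to_csv(trans_path, sep="\t", index=False)
        return [enr_path, model_path, trans_path]
    evidence["pav"] = evidence["lead_variant"].isin(pav_variants).astype(int)
    evidence["rare"] = (evidence["maf"] < 0.01).astype(int)
    evidence["large_beta"] = (evidence["beta_resc"].abs() > 0.5).astype(int)
    evidence = evidence.merge(gps[["gene_id", "gps", "ta_count"]], on="gene_id",
                              how="left").fillna({"gps": 1, "ta_count": 1})
    attached = tr.attach_genetic_support(ti, evidence, edges)
    results = [tr.fisher_enrichment(attached, "support")]
    for stratum in ("pav", "rare", "large_beta"):
        if attached[stratum].astype(bool).any() and attached[stratum].nunique() > 1:
            results.append(tr.fisher_enrichment(attached, stratum))
    enr = pd.DataFrame(
        [{"stratum": r.stratum, "a": r.a, "b": r.b, "c": r.c, "d": r.d,
          "odds_ratio": r.odds_ratio, "relative_success": r.relative_success,
          "fisher_p": r.fisher_p, "or_lo": r.or_ci[0], "or_hi": r.or_ci[1]}
         for r in results]
    )
    enr.to_csv(enr_path, sep="\t", index=False)
    model = tr.nonlinear_pleiotropy_model(attached, seed=seed)
    with open(model_path, "w") as fh:
        json.dump(
            {"loglik": model["loglik"],
             "p_linear_vs_baseline": model["p_linear_vs_baseline"],
             "p_quadratic_vs_linear": model["p_quadratic_vs_linear"],
             "coefficients": list(map(float, model["coefficients"]))},
            fh, indent=2, sort_keys=True,
        )
    trans = tr.phase_transitions(attached, group_col="ta_count")
    trans.to_csv(trans_path, sep="\t", index=False)
    out_paths += [enr_path, model_path, trans_path]
    return out_paths


# --------------------------------------------------------------------------- #
# run-all                                                                     #
# --------------------------------------------------------------------------- #


def run_all(
    config: SimulationConfig,
    out_dir: str | Path,
    stages: tuple[str, ...] = STAGES,
) -> dict:
    """Execute the pipeline stages in order; returns the run manifest."""
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    config.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg_yaml = out_dir / "_config_hash.yaml"
    config.to_yaml(cfg_yaml)
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config_sha256": _sha256(cfg_yaml),
        "stages": [],
        "started_utc": time.strftime("%Y-%m-%dT%H:%M:%SZ", time.gmtime()),
    }
    for stage in STAGES:
        if stage not in stages:
            continue
        if stage == "simulate":
            outputs = stage_simulate(config, out_dir)
        elif stage == "harmonise":
            outputs = stage_harmonise(out_dir)
        elif stage == "finemap":
            outputs = stage_finemap(out_dir)
        elif stage == "coloc":
            outputs = stage_coloc(out_dir)
        elif stage == "l2g":
            outputs = stage_l2g(out_dir, seed=config.seed)
        elif stage == "pleiotropy":
            outputs = stage_pleiotropy(out_dir)
        else:
            outputs = stage_translate(out_dir, seed=config.seed)
        manifest["stages"].append(
            {"stage": stage,
             "outputs": {str(p.relative_to(out_dir)): _sha256(p) for p in outputs}}
        )
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
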