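"""Locus-to-gene (L2G) prioritisation.

Builds the 28-feature credible-set x gene matrix, assembles a labelled
training set from gold-standard gene-trait pairs, trains a gradient-boosted
binary classifier and emits effector-gene selections.

Feature roster (12 individual features, their 12 neighbourhood counterparts,
plus four context features = 28):

* distanceSentinelTss / distanceMeanTss / distanceSentinelFootprint /
  distanceMeanFootprint -- distance score = 1 - min(d, 500 kb)/500 kb; mean
  features are PIP-weighted sums over credible-set variants, sentinel
  features use the lead variant;
* eQtlColocClppMaximum / eQtlColocH4Maximum and the pQTL / sQTL analogues --
  maximum colocalisation evidence linking the credible set to a molQTL of
  the gene;
* vepMean / vepMaximum -- PIP-weighted sum and maximum of variant
  pathogenicity scores on the gene;
* neighbourhood counterparts: individual value / max over candidate genes of
  the same credible set (0 when the max is 0);
* geneCountAll, geneCountProteinCoding (unscaled counts),
  credibleSetConfidence (fine-mapping method tier), isProteinCodingNearest.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics import average_precision_score, roc_auc_score
from sklearn.model_selection import GridSearchCV
from xgboost import XGBClassifier

from .harmonise import CredibleSet

DISTANCE_WINDOW = 500_000
METHOD_CONFIDENCE = {"susie": 1.0, "ingested": 0.75, "pics": 0.5}

INDIVIDUAL_FEATURES = [
    "distanceSentinelTss", "distanceMeanTss",
    "distanceSentinelFootprint", "distanceMeanFootprint",
    "eQtlColocClppMaximum", "eQtlColocH4Maximum",
    "pQtlColocClppMaximum", "pQtlColocH4Maximum",
    "sQtlColocClppMaximum", "sQtlColocH4Maximum",
    "vepMean", "vepMaximum",
]
NEIGHBOURHOOD_FEATURES = [f + "Neighbourhood" for f in INDIVIDUAL_FEATURES]
CONTEXT_FEATURES = [
    "geneCountAll", "geneCountProteinCoding", "credibleSetConfidence",
    "isProteinCodingNearest",
]
ALL_FEATURES = INDIVIDUAL_FEATURES + NEIGHBOURHOOD_FEATURES + CONTEXT_FEATURES


def distance_score(d: np.ndarray | float) -> np.ndarray | float:
    return 1.0 - np.minimum(np.abs(d), DISTANCE_WINDOW) / DISTANCE_WINDOW


def build_feature_matrix(
    cs_list: list[CredibleSet],
    genes: pd.DataFrame,
    variant_positions: pd.DataFrame,
    coloc_df: pd.DataFrame | None = None,
    molqtl_gene_of_cs: dict[str, tuple[str, str]] | None = None,
    vep_scores: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """One row per (credible set, candidate gene within +/- 500 kb).

    ``genes``: gene_id, chrom, tss, start, end, protein_coding.
    ``variant_positions``: variant_id, chrom, pos.
    ``coloc_df``: output of :func:`pleiomap.coloc.coloc_results_frame`.
    ``molqtl_gene_of_cs``: molQTL cs_id -> (gene_id, qtl_type).
    ``vep_scores``: variant_id, gene_id, pathogenicity.
    """
    vpos = variant_positions.set_index("variant_id")
    vep = (
        vep_scores.set_index(["variant_id", "gene_id"])["pathogenicity"]
        if vep_scores is not None else None
    )
    coloc_by_gwas_cs: dict[str, list[tuple[str, str, float, float]]] = {}
    if coloc_df is not None and molqtl_gene_of_cs:
        for _, r in coloc_df.iterrows():
            for gwas_side, mol_side in ((r["left_cs_id"], r["right_cs_id"]),
                                        (r["right_cs_id"], r["left_cs_id"])):
                if mol_side in molqtl_gene_of_cs and gwas_side not in molqtl_gene_of_cs:
                    g, qtl = molqtl_gene_of_cs[mol_side]
                    coloc_by_gwas_cs.setdefault(gwas_side, []).append(
                        (g, qtl, float(r["clpp"]), float(r.get("h4", np.nan)))
                    )
    rows = []
    for cs in cs_list:
        chrom, start, end = cs.region
        cand = genes[
            (genes["chrom"] == chrom)
            & (genes["tss"] >= start - DISTANCE_WINDOW)
            & (genes["tss"] <= end + DISTANCE_WINDOW)
        ]
        if cand.empty:
            continue
        lead_pos = int(vpos.loc[cs.lead_variant, "pos"])
        member_pos = np.array([int(vpos.loc[v, "pos"]) for v, _ in cs.members])
        pips = np.array([p for _, p in cs.members])
        wsum = pips.sum()
        nearest_gene = cand.iloc[(cand["tss"] - lead_pos).abs().argsort().iloc[0]]
        n_all = len(cand)
        n_pc = int(cand["protein_coding"].sum())
        for _, g in cand.iterrows():
            tss, gstart, gend = int(g["tss"]), int(g["start"]), int(g["end"])

            def foot_d(p):
                return 0 if gstart <= p <= gend else min(abs(p - gstart), abs(p - gend))

            feat = {
                "cs_id": cs.cs_id, "gene_id": g["gene_id"],
                "protein_coding": bool(g["protein_coding"]),
                "distanceSentinelTss": float(distance_score(lead_pos - tss)),
                "distanceMeanTss": float(
                    (pips * distance_score(member_pos - tss)).sum() / wsum
                ),
                "distanceSentinelFootprint": float(distance_score(foot_d(lead_pos))),
                "distanceMeanFootprint": float(
                    (pips * distance_score(np.array([foot_d(p) for p in member_pos]))).sum()
                    / wsum
                ),
                "credibleSetConfidence": METHOD_CONFIDENCE.get(cs.method, 0.25),
                "isProteinCodingNearest": float(
                    bool(g["protein_coding"]) and g["gene_id"] == nearest_gene["gene_id"]
                ),
                "geneCountAll": float(n_all),
                "geneCountProteinCoding": float(n_pc),
            }
            for qtl, tag in (("eqtl", "eQtl"), ("pqtl", "pQtl"), ("sqtl", "sQtl")):
                links = [
                    (c, h) for gg, q, c, h in coloc_by_gwas_cs.get(cs.cs_id, [])
                    if gg == g["gene_id"] and q == qtl
                ]
                feat[f"{tag}ColocClppMaximum"] = max((c for c, _ in links), default=0.0)
                feat[f"{tag}ColocH4Maximum"] = max(
                    (h for _, h in links if np.isfinite(h)), default=0.0
                )
            if vep is not None:
                scores = np.array([
                    float(vep.get((v, g["gene_id"]), 0.0)) for v, _ in cs.members
                ])
                feat["vepMean"] = float((pips * scores).sum() / wsum)
                feat["vepMaximum"] = float(scores.max()) if len(scores) else 0.0
            else:
                feat["vepMean"] = feat["vepMaximum"] = 0.0
            rows.append(feat)
    fm = pd.DataFrame(rows)
    if fm.empty:
        return fm
    for f in INDIVIDUAL_FEATURES:
        mx = fm.groupby("cs_id")[f].transform("max")
        fm[f + "Neighbourhood"] = np.where(mx > 0, fm[f] / mx, 0.0)
    return fm.fillna(0.0)


# --------------------------------------------------------------------------- #
# training set                                                                #
# --------------------------------------------------------------------------- #


@dataclass
class GoldStandardPair:
    gene_id: str
    trait_id: str
    source: str = "curated"  # curated | clinical_phase34 | high_confidence_rare
    confidence: str = "high"


def dedupe_gold_standards(pairs: list[GoldStandardPair]) -> list[GoldStandardPair]:
    seen, out = set(), []
    for p in pairs:
        key = (p.gene_id, p.trait_id)
        if key not in seen:
            seen.add(key)
            out.append(p)
    return out


def assemble_training_set(
    gold: list[GoldStandardPair],
    feature_matrix: pd.DataFrame,
    cs_traits: dict[str, str],
    test_fraction: float = 0.2,
    seed: int = 0,
) -> pd.DataFrame:
    """Label feature rows and split 80/20 by unique positive genes.

    Positives: rows whose (gene, trait-of-credible-set) matches a
    deduplicated gold standard.  Negatives: all other protein-coding genes on
    a credible set that has at least one positive.  Credible sets sharing a
    positive gene always land in the same partition.
    """
    gold = dedupe_gold_standards(gold)
    gold_keys = {(p.gene_id, p.trait_id) for p in gold}
    fm = feature_matrix.copy()
    fm["trait_id"] = fm["cs_id"].map(cs_traits)
    fm["label"] = [
        "positive" if (g, t) in gold_keys else "unlabelled"
        for g, t in zip(fm["gene_id"], fm["trait_id"])
    ]
    pos_cs = set(fm.loc[fm["label"] == "positive", "cs_id"])
    fm.loc[
        (fm["cs_id"].isin(pos_cs)) & (fm["label"] != "positive") & fm["protein_coding"],
        "label",
    ] = "negative"
    labelled = fm[fm["label"] != "unlabelled"].copy()
    # group credible sets linked through shared positive genes (union-find) so
    # no positive gene spans the train/test boundary
    parent: dict[str, str] = {}

    def find(x):
        parent.setdefault(x, x)
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a, b):
        parent[find(a)] = find(b)

    pos_rows = labelled[labelled["label"] == "positive"]
    for _, r in pos_rows.iterrows():
        union(f"cs:{r['cs_id']}", f"gene:{r['gene_id']}")
    groups: dict[str, set[str]] = {}
    for cs_id in pos_cs:
        groups.setdefault(find(f"cs:{cs_id}"), set()).add(cs_id)
    rng = np.random.default_rng(seed)
    group_list = sorted(groups.values(), key=lambda s: sorted(s)[0])
    rng.shuffle(group_list)
    genes_of = [
        set(pos_rows.loc[pos_rows["cs_id"].isin(g), "gene_id"]) for g in group_list
    ]
    total_genes = len(set().union(*genes_of)) if genes_of else 0
    test_cs: set[str] = set()
    covered: set[str] = set()
    for grp, gset in zip(group_list, genes_of):
        if total_genes and len(covered) / total_genes < test_fraction:
            test_cs |= grp
            covered |= gset
    labelled["split"] = np.where(labelled["cs_id"].isin(test_cs), "test", "train")
    return labelled


# --------------------------------------------------------------------------- #
# classifier                                                                  #
# --------------------------------------------------------------------------- #


class L2GClassifier(BaseEstimator, ClassifierMixin):
    """Gradient-boosted L2G binary classifier (xgboost backend).

    Optionally runs a small cross-validated grid search over depth, learning
    rate and number of trees selected by average precision.
    """

    def __init__(self, tune: bool = False, random_state: int = 0, n_estimators: int = 200,
                 max_depth: int = 4, learning_rate: float = 0.1):
        self.tune = tune
        self.random_state = random_state
        self.n_estimators = n_estimators
        self.max_depth = max_depth
        self.learning_rate = learning_rate

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        base = XGBClassifier(
            n_estimators=self.n_estimators, max_depth=self.max_depth,
            learning_rate=self.learning_rate, random_state=self.random_state,
            eval_metric="logloss", n_jobs=1,
        )
        if self.tune:
            grid = {"max_depth": [3, 5], "learning_rate": [0.05, 0.2],
                    "n_estimators": [100, 300]}
            search = GridSearchCV(base, grid, scoring="average_precision", cv=3, n_jobs=1)
            search.fit(X, y)
            self.model_ = search.best_estimator_
            self.best_params_ = search.best_params_
        else:
            base.fit(X, y)
            self.model_ = base
        self.classes_ = np.unique(y)
        return self

    def predict_proba(self, X):
        return self.model_.predict_proba(np.asarray(X, dtype=float))

    def predict(self, X):
        return self.model_.predict(np.asarray(X, dtype=float))


def train_and_score(
    labelled: pd.DataFrame,
    tune: bool = False,
    seed: int = 0,
    score_threshold: float = 0.5,
) -> tuple[pd.DataFrame, dict[str, float], L2GClassifier]:
    """Fit on the training partition, report held-out metrics, score all rows.

    Returns (scored table, metrics {average_precision, auc, recall_at_half,
    fdr_at_half}, fitted classifier).
    """
    train = labelled[labelled["split"] == "train"]
    test = labelled[labelled["split"] == "test"]
    if train.empty:
        raise ValueError("empty training partition")
    ytr = (train["label"] == "positive").astype(int).to_numpy()
    clf = L2GClassifier(tune=tune, random_state=seed).fit(train[ALL_FEATURES], ytr)
    scored = labelled.copy()
    scored["l2g_score"] = clf.predict_proba(labelled[ALL_FEATURES])[:, 1]
    metrics: dict[str, float] = {}
    if not test.empty and test["label"].nunique() > 1:
        yte = (test["label"] == "positive").astype(int).to_numpy()
        ste = scored.loc[test.index, "l2g_score"].to_numpy()
        sel = ste >= score_threshold
        metrics = {
            "average_precision": float(average_precision_score(yte, ste)),
            "auc": float(roc_auc_score(yte, ste)),
            "recall_at_half": float(sel[yte == 1].mean()) if (yte == 1).any() else np.nan,
            "fdr_at_half": float(1.0 - yte[sel].mean()) if sel.any() else np.nan,
        }
    return scored, metrics, clf


def select_effector_genes(
    scores: pd.DataFrame, threshold: float = 0.5, fallback: float = 0.1
) -> pd.DataFrame:
    """Per credible set: every gene scoring >= 0.5; if none, the top-ranked
    gene provided it scores >= 0.1; otherwise no assignment."""
    out = []
    for cs_id, grp in scores.groupby("cs_id"):
        hits = grp[grp["l2g_score"] >= threshold]
        if hits.empty:
            top = grp.sort_values(["l2g_score", "gene_id"], ascending=[False, True]).iloc[:1]
            hits = top[top["l2g_score"] >= fallback]
        for _, r in hits.iterrows():
            out.append({"cs_id": cs_id, "gene_id": r["gene_id"],
                        "l2g_score": float(r["l2g_score"])})
    return pd.DataFrame(out, columns=["cs_id", "gene_id", "l2g_score"])
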