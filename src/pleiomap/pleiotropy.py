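"""Variant- and gene-level pleiotropy scoring and its covariate models.

Disease credible sets are clustered through colocalisation: starting from the
most strongly associated unassigned credible set, all significantly
colocalised sets are pulled in, the union of their lead variants is taken,
every remaining set sharing one of those lead variants joins, and the
expansion is iterated to a fixed point.  The variant pleiotropy score (vPS) of
a cluster is its number of unique diseases (union over all lead variants);
the gene pleiotropy score (gPS) counts unique diseases over all prioritised
variants sharing a likely causal gene.

Count models are negative-binomial GLMs on min-max scaled covariates, with
Pearson R^2 between predicted and observed counts as the accuracy measure and
leave-one-covariate-out R^2 deltas as variance-explained contributions.
Gene-set enrichment is a per-set logistic regression of membership on
log2(gPS) with Wald tests and Benjamini-Hochberg correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from ._utils import bh_adjust


@dataclass
class VariantCluster:
    cluster_id: str
    member_cs_ids: list[str]
    lead_variants: set[str]
    diseases: set[str] = field(default_factory=set)
    tas: set[str] = field(default_factory=set)

    @property
    def vps(self) -> int:
        return len(self.diseases)

    @property
    def ta_count(self) -> int:
        return len(self.tas)


def cluster_credible_sets(
    cs_table: pd.DataFrame, coloc_pairs: set[tuple[str, str]]
) -> list[VariantCluster]:
    """Partition disease credible sets into colocalisation clusters.

    ``cs_table``: cs_id, lead_variant, lead_p, trait_id, ta and optionally
    beta_resc (tie-break).  ``coloc_pairs``: unordered significant pairs.

    Seeds are taken in order of smallest lead p (ties: larger |beta_resc|,
    then cs_id); expansion alternates colocalisation edges and shared-lead
    edges until a fixed point.
    """
    required = {"cs_id", "lead_variant", "lead_p", "trait_id"}
    missing = required - set(cs_table.columns)
    if missing:
        raise ValueError(f"cs table missing columns {sorted(missing)}")
    df = cs_table.copy()
    if "beta_resc" not in df.columns:
        df["beta_resc"] = 0.0
    df["_absb"] = -df["beta_resc"].abs()
    order = df.sort_values(["lead_p", "_absb", "cs_id"], kind="mergesort")["cs_id"].tolist()
    coloc_edges: dict[str, set[str]] = {}
    for a, b in coloc_pairs:
        coloc_edges.setdefault(a, set()).add(b)
        coloc_edges.setdefault(b, set()).add(a)
    lead_of = dict(zip(df["cs_id"], df["lead_variant"]))
    by_lead: dict[str, set[str]] = {}
    for cs_id, lv in lead_of.items():
        by_lead.setdefault(lv, set()).add(cs_id)
    info = df.set_index("cs_id")
    unassigned = set(df["cs_id"])
    clusters = []
    k = 0
    for seed in order:
        if seed not in unassigned:
            continue
        members = {seed}
        while True:
            expanded = set(members)
            for cs_id in members:
                expanded |= coloc_edges.get(cs_id, set()) & unassigned
            leads = {lead_of[c] for c in expanded}
            for lv in leads:
                expanded |= by_lead[lv] & unassigned
            if expanded == members:
                break
            members = expanded
        k += 1
        sub = info.loc[sorted(members)]
        clusters.append(
            VariantCluster(
                cluster_id=f"VC{k:05d}",
                member_cs_ids=sorted(members),
                lead_variants={lead_of[c] for c in members},
                diseases=set(sub["trait_id"]),
                tas=set(sub["ta"]) if "ta" in sub.columns else set(),
            )
        )
        unassigned -= members
    return clusters


def compute_vps(cluster: VariantCluster) -> tuple[int, int]:
    """(vPS, TA count): unique diseases / therapeutic areas in the cluster."""
    return cluster.vps, cluster.ta_count


def beta_concordance(signs) -> float:
    """Largest proportion of same-direction effects; 1 for a single
    association, in [0.5, 1] otherwise."""
    s = [x for x in signs]
    if not s:
        raise ValueError("no associations")
    if any(x not in (-1, 1, -1.0, 1.0, "+", "-") for x in s):
        raise ValueError("all signs must be usable (+/-)")
    pos = sum(1 for x in s if x in (1, 1.0, "+"))
    neg = len(s) - pos
    return max(pos, neg) / len(s)


def compute_gps(prioritisations: pd.DataFrame) -> pd.DataFrame:
    """Per-gene pleiotropy: unique diseases (gPS) and TAs over all prioritised
    variants.  ``prioritisations``: gene_id, trait_id, ta (one row per
    prioritised credible-set/variant association)."""
    required = {"gene_id", "trait_id"}
    if required - set(prioritisations.columns):
        raise ValueError("prioritisations need gene_id and trait_id")
    gp = prioritisations.groupby("gene_id").agg(
        gps=("trait_id", "nunique"),
        ta_count=("ta", "nunique") if "ta" in prioritisations.columns else ("trait_id", "nunique"),
    )
    return gp.reset_index()


# --------------------------------------------------------------------------- #
# tissue specificity                                                          #
# --------------------------------------------------------------------------- #


def score_tissue_specificity(expression: pd.Series) -> tuple[float, int] | None:
    """(score, binary) from a gene's per-tissue expression profile.

    enriched (>= 4x every other tissue) -> 1; group enriched (2-5 tissues each
    >= 4x all others) -> 0.75; enhanced (>= 4x the mean of the others) -> 0.5;
    else -1.  binary = 1 iff score > 0.75.  Undetected genes (all zero)
    return None.
    """
    x = np.asarray(expression, dtype=float)
    if len(x) < 2 or np.all(x == 0):
        return None
    order = np.argsort(-x)
    xs = x[order]
    score = -1.0
    if xs[0] >= 4.0 * xs[1]:
        score = 1.0
    else:
        for g in range(2, min(5, len(x) - 1) + 1):
            if g >= len(x):
                break
            if xs[g - 1] > 0 and xs[g - 1] >= 4.0 * xs[g]:
                score = 0.75
                break
        if score < 0:
            for i in range(len(x)):
                others = np.delete(x, i)
                if x[i] >= 4.0 * others.mean():
                    score = 0.5
                    break
    return score, int(score > 0.75)


# --------------------------------------------------------------------------- #
# count models                                                                #
# --------------------------------------------------------------------------- #


def minmax_scale_covariates(cov: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Scale each covariate to [0, 1]; constant covariates are dropped with a
    warning and reported."""
    out = {}
    dropped = []
    for c in cov.columns:
        x = cov[c].astype(float)
        lo, hi = x.min(), x.max()
        if hi - lo <= 0:
            warnings.warn(f"covariate {c} is constant; dropped from model")
            dropped.append(c)
            continue
        out[c] = (x - lo) / (hi - lo)
    return pd.DataFrame(out, index=cov.index), dropped


def _fit_nb(y: np.ndarray, X: np.ndarray):
    """Negative binomial (ML dispersion) with a Poisson fallback when the
    dispersion estimate diverges."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.NegativeBinomial(y, X).fit(disp=0, maxiter=200)
            alpha = float(res.params[-1])
            if np.isfinite(res.llf) and 1e-8 < alpha < 1e4:
                return res, "negative_binomial"
        except Exception:
            pass
        return sm.Poisson(y, X).fit(disp=0, maxiter=200), "poisson"


def _pearson_r2(y: np.ndarray, mu: np.ndarray) -> float:
    if np.std(mu) == 0 or np.std(y) == 0:
        return 0.0
    return float(np.corrcoef(y, mu)[0, 1] ** 2)


def fit_count_model(
    counts: pd.Series | np.ndarray,
    covariates: pd.DataFrame,
    mode: str = "joint",
) -> dict:
    """NB-GLM (log link) of a pleiotropy count on scaled covariates.

    mode 'joint': one model with all covariates, plus leave-one-out
    variance-explained deltas; mode 'univariate': one model per covariate.
    Returns coefficients, family used, Pearson R^2 and deltas.
    """
    y = np.asarray(counts, dtype=float)
    if np.any(y < 0) or np.any(y != np.round(y)):
        raise ValueError("counts must be non-negative integers")
    Xs, dropped = minmax_scale_covariates(covariates)
    if Xs.empty:
        raise ValueError("no usable covariates after scaling")
    result: dict = {"dropped": dropped, "mode": mode}
    if mode == "univariate":
        rows = []
        for c in Xs.columns:
            X = sm.add_constant(Xs[[c]].to_numpy())
            res, fam = _fit_nb(y, X)
            mu = np.asarray(res.predict(X))
            rows.append({"covariate": c, "coef": float(res.params[1]),
                         "se": float(res.bse[1]), "p": float(res.pvalues[1]),
                         "family": fam, "pearson_r2": _pearson_r2(y, mu)})
        result["univariate"] = pd.DataFrame(rows)
        return result
    X = sm.add_constant(Xs.to_numpy())
    res, fam = _fit_nb(y, X)
    mu = np.asarray(res.predict(X))
    full_r2 = _pearson_r2(y, mu)
    coefs = pd.DataFrame({
        "covariate": list(Xs.columns),
        "coef": res.params[1: 1 + Xs.shape[1]],
        "se": res.bse[1: 1 + Xs.shape[1]],
        "p": res.pvalues[1: 1 + Xs.shape[1]],
    })
    deltas = {}
    for c in Xs.columns:
        Xm = sm.add_constant(Xs.drop(columns=c).to_numpy())
        res_m, _ = _fit_nb(y, Xm)
        deltas[c] = full_r2 - _pearson_r2(y, np.asarray(res_m.predict(Xm)))
    alpha = float(res.params[-1]) if fam == "negative_binomial" else 0.0
    result.update({"coefficients": coefs, "family": fam, "dispersion": alpha,
                   "pearson_r2": full_r2, "r2_deltas": deltas})
    return result


# --------------------------------------------------------------------------- #
# gene-set enrichment                                                         #
# --------------------------------------------------------------------------- #


def gene_set_enrichment(
    gps_table: pd.DataFrame,
    gene_sets: dict[str, set[str]],
    protein_coding: set[str] | None = None,
) -> pd.DataFrame:
    """Per-set logistic regression of membership on log2(gPS).

    Background = all disease-associated genes in ``gps_table`` (gene_id, gps);
    non-protein-coding genes are removed when a coding set is supplied.  Sets
    with no overlap or no variation are skipped with a logged reason.
    """
    bg = gps_table.copy()
    if protein_coding is not None:
        bg = bg[bg["gene_id"].isin(protein_coding)]
    x = np.log2(bg["gps"].astype(float).to_numpy())
    rows = []
    for name, members in sorted(gene_sets.items()):
        y = bg["gene_id"].isin(members).astype(int).to_numpy()
        if y.sum() == 0:
            warnings.warn(f"gene set {name} has no overlap with the background; skipped")
            continue
        if y.sum() == len(y) or np.std(x) == 0:
            warnings.warn(f"gene set {name} degenerate (no contrast); skipped")
            continue
        X = sm.add_constant(x)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
        rows.append({"gene_set": name, "n_members": int(y.sum()),
                     "log_odds": float(res.params[1]), "se": float(res.bse[1]),
                     "p": float(res.pvalues[1])})
    out = pd.DataFrame(rows)
    if not out.empty:
        out["q"] = bh_adjust(out["p"].to_numpy())
    return out
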