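"""Locus definition and PICS fine-mapping.

Three clumping strategies define loci from summary statistics:

* distance clumping -- greedy +/- 500 kb windows around the most significant
  genome-wide significant variant;
* LD clumping -- greedy absorption of variants with r^2 >= 0.5 to the current
  top variant;
* locus breaker -- distance clumping, then clustering of sub-threshold
  (p < 1e-5) variants within 250 kb gaps, keeping clusters with at least one
  genome-wide significant variant, and splitting clusters over 1.5 Mb into
  +/- 750 kb sub-loci around the distance-clump leads.

PICS assigns each r^2 >= 0.5 proxy of the lead a causal probability from the
lead's -log10 p (S): the proxy's expected -log10 p is r^2 * S with standard
deviation sqrt(1 - r^k) * sqrt(S) / 2 (k = 6.4); the relative probability is
the two-sided upper-tail mass of that normal at S, which equals 1 for the lead
itself and decays with r^2.  Probabilities are normalised over the proxy set
and the 95% credible set is the smallest descending-probability prefix
reaching 0.95.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .harmonise import CredibleSet

GWS_P = 1e-8


@dataclass
class Locus:
    chrom: str
    start: int
    end: int
    top_variant: str
    members: pd.DataFrame  # variant_id, chromosome, base_pair_location, p_value, ...
    origin: str  # distance | ld | locus_breaker

    def __post_init__(self):
        top = self.members.set_index("variant_id").loc[self.top_variant]
        if not self.start <= int(top["base_pair_location"]) <= self.end:
            raise ValueError("top variant outside locus bounds")


def _most_significant(df: pd.DataFrame) -> pd.Series:
    """Deterministic 'most significant': smallest p, ties by larger |beta|,
    then lexicographic variant id."""
    key = df.assign(
        _absb=-(df["beta"].abs() if "beta" in df.columns else 0.0)
    ).sort_values(["p_value", "_absb", "variant_id"], kind="mergesort")
    return df.loc[key.index[0]]


def clump_by_distance(
    sumstats: pd.DataFrame, window: int = 500_000, gws_p: float = GWS_P
) -> list[Locus]:
    loci = []
    for chrom, chrom_df in sumstats.groupby("chromosome", sort=True):
        remaining = chrom_df.copy()
        while True:
            gws = remaining[remaining["p_value"] <= gws_p]
            if gws.empty:
                break
            top = _most_significant(gws)
            pos = int(top["base_pair_location"])
            in_win = (remaining["base_pair_location"] - pos).abs() <= window
            members = remaining[in_win]
            loci.append(
                Locus(str(chrom), int(members["base_pair_location"].min()),
                      int(members["base_pair_location"].max()),
                      top["variant_id"], members.reset_index(drop=True), "distance")
            )
            remaining = remaining[~in_win]
    return loci


def clump_by_ld(
    sumstats: pd.DataFrame, ld: pd.DataFrame, r2_min: float = 0.5, gws_p: float = GWS_P
) -> list[Locus]:
    """Greedy by significance; r^2 is the square of the signed r in ``ld``."""
    loci = []
    for chrom, chrom_df in sumstats.groupby("chromosome", sort=True):
        remaining = chrom_df.copy()
        while True:
            gws = remaining[remaining["p_value"] <= gws_p]
            if gws.empty:
                break
            top = _most_significant(gws)
            vid = top["variant_id"]
            if vid not in ld.index:
                raise KeyError(f"LD not available for genome-wide significant variant {vid}")
            r2 = (ld[vid] ** 2).reindex(remaining["variant_id"]).fillna(0.0).to_numpy()
            absorb = r2 >= r2_min
            members = remaining[absorb]
            loci.append(
                Locus(str(chrom), int(members["base_pair_location"].min()),
                      int(members["base_pair_location"].max()),
                      vid, members.reset_index(drop=True), "ld")
            )
            remaining = remaining[~absorb]
    return loci


def locus_breaker(
    sumstats: pd.DataFrame,
    p_cluster: float = 1e-5,
    gap: int = 250_000,
    gws_p: float = GWS_P,
    max_span: int = 1_500_000,
    half_window: int = 750_000,
) -> list[Locus]:
    loci: list[Locus] = []
    for chrom, chrom_df in sumstats.groupby("chromosome", sort=True):
        # step 1: distance clumping gives the lead SNPs used for splitting
        step1 = clump_by_distance(chrom_df, gws_p=gws_p)
        leads = [lo.top_variant for lo in step1]
        # step 2: cluster p < 1e-5 variants with inter-variant gaps <= 250 kb
        sub = chrom_df[chrom_df["p_value"] < p_cluster].sort_values("base_pair_location")
        if sub.empty:
            continue
        pos = sub["base_pair_location"].to_numpy()
        breaks = np.flatnonzero(np.diff(pos) > gap)
        cluster_ids = np.zeros(len(sub), dtype=int)
        for b in breaks:
            cluster_ids[b + 1:] += 1
        sub = sub.assign(_cluster=cluster_ids)
        for _, cl in sub.groupby("_cluster"):
            if (cl["p_value"] > gws_p).all():
                continue  # cluster must contain a genome-wide significant variant
            span = int(cl["base_pair_location"].max() - cl["base_pair_location"].min())
            if span <= max_span:
                top = _most_significant(cl[cl["p_value"] <= gws_p])
                loci.append(
                    Locus(str(chrom), int(cl["base_pair_location"].min()),
                          int(cl["base_pair_location"].max()), top["variant_id"],
                          cl.drop(columns="_cluster").reset_index(drop=True), "locus_breaker")
                )
            else:
                # step 3: split around the step-1 lead SNPs inside the cluster
                in_cluster = cl.set_index("variant_id")
                for lead in leads:
                    if lead not in in_cluster.index:
                        continue
                    lpos = int(in_cluster.loc[lead, "base_pair_location"])
                    m = cl[(cl["base_pair_location"] - lpos).abs() <= half_window]
                    loci.append(
                        Locus(str(chrom), int(m["base_pair_location"].min()),
                              int(m["base_pair_location"].max()), lead,
                              m.drop(columns="_cluster").reset_index(drop=True),
                              "locus_breaker")
                    )
    for lo in loci:
        assert lo.end - lo.start <= max_span
    return loci


# --------------------------------------------------------------------------- #
# PICS                                                                        #
# --------------------------------------------------------------------------- #


def pics_probabilities(
    neglog_p_lead: float, r2: np.ndarray, k_exponent: float = 6.4
) -> np.ndarray:
    """Normalised PICS causal probabilities for proxies with the given r^2.

    Relative probability of a proxy = 2 * (1 - Phi((S - mu)/sigma)) with
    mu = r^2 S, sigma = sqrt(1 - r^k) sqrt(S)/2; equals 1 at r^2 = 1.
    """
    r2 = np.asarray(r2, dtype=float)
    s = float(neglog_p_lead)
    mu = r2 * s
    sigma = np.sqrt(np.clip(1.0 - r2 ** (k_exponent / 2.0), 0.0, None)) * np.sqrt(s) / 2.0
    rel = np.where(sigma > 0, 2.0 * norm.sf(s, loc=mu, scale=np.where(sigma > 0, sigma, 1.0)), 1.0)
    total = rel.sum()
    if total <= 0:
        raise ValueError("degenerate PICS weights")
    return rel / total


def pics_finemap(
    locus: Locus,
    ld_row: pd.Series,
    r2_min: float = 0.5,
    k_exponent: float = 6.4,
    cs_id: str | None = None,
    study_id: str = "",
) -> CredibleSet:
    """95% credible set from the lead's LD proxies (r^2 >= ``r2_min``)."""
    lead = locus.top_variant
    if lead not in ld_row.index:
        raise KeyError(f"lead variant {lead} missing from LD")
    members = locus.members.set_index("variant_id")
    proxies = [v for v in members.index if v in ld_row.index and ld_row[v] ** 2 >= r2_min]
    if lead not in proxies:
        proxies.append(lead)
    r2 = np.array([ld_row[v] ** 2 for v in proxies])
    neglog_p = -np.log10(float(members.loc[lead, "p_value"]))
    probs = pics_probabilities(neglog_p, r2, k_exponent)
    order = np.argsort(-probs, kind="stable")
    kept, cum = [], 0.0
    for i in order:
        kept.append((proxies[i], float(probs[i])))
        cum += probs[i]
        if cum >= 0.95:
            break
    lead_beta = float(members.loc[lead, "beta"]) if "beta" in members.columns else np.nan
    cs = CredibleSet(
        cs_id=cs_id or f"PICS:{lead}",
        study_id=study_id,
        lead_variant=max(kept, key=lambda t: t[1])[0],
        members=kept,
        method="pics",
        lead_p=float(members.loc[lead, "p_value"]),
        beta_sign=("+" if lead_beta > 0 else "-") if np.isfinite(lead_beta) else "unknown",
        region=(locus.chrom, locus.start, locus.end),
        lead_beta=lead_beta,
    )
    cs.validate()
    return cs


# --------------------------------------------------------------------------- #
# lead p-value thresholds                                                     #
# --------------------------------------------------------------------------- #

LEAD_P_THRESHOLDS = {"gwas": 1e-5, "molqtl": 1e-3}


def apply_lead_p_threshold(
    cs_list: list[CredibleSet],
    source_class: str,
    study_overrides: dict[str, float] | None = None,
) -> list[CredibleSet]:
    """Keep credible sets whose lead p passes the class threshold (GWAS 1e-5,
    molQTL 1e-3); per-study overrides (e.g. 1.7e-11) take precedence."""
    if source_class not in LEAD_P_THRESHOLDS:
        raise ValueError(f"unknown source class {source_class}")
    overrides = study_overrides or {}
    out = []
    for cs in cs_list:
        thr = overrides.get(cs.study_id, LEAD_P_THRESHOLDS[source_class])
        if cs.lead_p <= thr:
            out.append(cs)
    return out
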