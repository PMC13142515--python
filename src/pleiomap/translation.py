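"""Genetic support and clinical success.

Joins gene-disease genetic evidence to target-indication (T-I) clinical
records (evidence on descendants of the indication counts as support;
oncology indications are excluded) and quantifies enrichment of genetic
support in approval:

* Fisher's exact test on the 2x2 table of support x approval, with
  OR = ad/bc and relative success RS = P(approved | support) /
  P(approved | no support);
* stratified logistic comparisons of two evidence classes with a t-test on
  the coefficient difference and Benjamini-Hochberg correction;
* nested logistic models of approval on genetic support plus
  log(uniqueDiseases + 1) and its square, compared by likelihood-ratio
  tests, with percentile-bootstrap prediction bands (200 resamples) and a
  LOWESS curve;
* phase-transition probabilities P(II|I), P(III|II), P(approval|III) per
  pleiotropy group with Wilson 95% intervals and BH-corrected pairwise
  two-proportion tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.stats.contingency import odds_ratio as _cmle_odds_ratio

from ._utils import bh_adjust
from .harmonise import ancestors

PLEIOTROPY_GROUPS = (("low", 1, 1), ("medium", 2, 5), ("high", 6, None))


# --------------------------------------------------------------------------- #
# evidence attachment                                                         #
# --------------------------------------------------------------------------- #


def descendants_closure(parent_edges: dict[str, list[str]]) -> dict[str, set[str]]:
    """term -> set of descendants (term included) from child->parent edges."""
    children: dict[str, set[str]] = {}
    terms = set(parent_edges)
    for c, ps in parent_edges.items():
        for p in ps:
            children.setdefault(p, set()).add(c)
            terms.add(p)
    out = {}
    for t in terms:
        seen, frontier = {t}, [t]
        while frontier:
            nxt = []
            for x in frontier:
                for ch in children.get(x, ()):  # descend
                    if ch not in seen:
                        seen.add(ch)
                        nxt.append(ch)
            frontier = nxt
        out[t] = seen
    return out


def attach_genetic_support(
    ti: pd.DataFrame,
    evidence: pd.DataFrame,
    parent_edges: dict[str, list[str]],
    oncology_root: str = "cell proliferation disorder",
) -> pd.DataFrame:
    """Flag each T-I record with genetic-support strata.

    ``ti``: target_id, indication_id, max_phase.  ``evidence``: gene_id,
    trait_id plus optional boolean/numeric stratum columns (pav, rare,
    large_beta, rare_disease_resource) and per-gene counts (gps, ta_count).
    Evidence on the indication or any of its descendants counts as support;
    indications under the oncology root are removed.
    """
    desc = descendants_closure(parent_edges)
    out = ti.copy()
    onc = out["indication_id"].map(
        lambda t: oncology_root in ancestors(t, parent_edges)
    )
    if "oncology" in out.columns:
        onc = onc | out["oncology"].astype(bool)
    out = out[~onc].copy()
    ev_by_gene: dict[str, pd.DataFrame] = {g: d for g, d in evidence.groupby("gene_id")}
    flag_cols = [c for c in ("pav", "rare", "large_beta", "rare_disease_resource")
                 if c in evidence.columns]
    count_cols = [c for c in ("gps", "ta_count") if c in evidence.columns]
    records = []
    for _, r in out.iterrows():
        ev = ev_by_gene.get(r["target_id"])
        rec = {"support": 0, **{c: 0 for c in flag_cols}, **{c: 0 for c in count_cols}}
        if ev is not None:
            allowed = desc.get(r["indication_id"], {r["indication_id"]})
            hit = ev[ev["trait_id"].isin(allowed)]
            if not hit.empty:
                rec["support"] = 1
                for c in flag_cols:
                    rec[c] = int(hit[c].astype(bool).any())
                for c in count_cols:
                    rec[c] = int(hit[c].max())
        records.append(rec)
    flags = pd.DataFrame(records, index=out.index)
    out = out.drop(columns=[c for c in flags.columns if c in out.columns])
    out = pd.concat([out, flags], axis=1)
    out["approved"] = (out["max_phase"] == 4).astype(int)
    return out


def define_strict_support(evidence: pd.DataFrame) -> pd.Series:
    """PAV-supported and genetic support in 2 to 5 therapeutic areas."""
    for c in ("pav", "ta_count"):
        if c not in evidence.columns:
            raise ValueError(f"evidence table missing column {c}")
    return (
        evidence["pav"].astype(bool)
        & evidence["ta_count"].between(2, 5)
    ).astype(int)


# --------------------------------------------------------------------------- #
# Fisher enrichment                                                           #
# --------------------------------------------------------------------------- #


def wilson_interval(k: int, n: int, conf: float = 0.95) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion (closed form)."""
    if n <= 0:
        raise ValueError("n must be positive")
    z = stats.norm.ppf(0.5 + conf / 2.0)
    phat = k / n
    denom = 1.0 + z**2 / n
    centre = (phat + z**2 / (2 * n)) / denom
    half = z * np.sqrt(phat * (1 - phat) / n + z**2 / (4 * n**2)) / denom
    return max(0.0, centre - half), min(1.0, centre + half)


@dataclass
class EnrichmentResult:
    stratum: str
    a: int  # support & approved
    b: int  # support & not approved
    c: int  # no support & approved
    d: int  # no support & not approved
    odds_ratio: float
    relative_success: float
    fisher_p: float
    or_ci: tuple[float, float]
    rs_ci: tuple[float, float]

    @property
    def table(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])


def enrichment_from_table(a: int, b: int, c: int, d: int,
                          stratum: str = "") -> EnrichmentResult:
    """OR, RS and Fisher p from a 2x2 table (rows: support yes/no; columns:
    approved yes/no).  Zero cells: exact Fisher p is still reported; the OR
    falls back to the conditional MLE (0 and inf limits apply)."""
    table = np.array([[a, b], [c, d]])
    if table.sum() == 0:
        raise ValueError("empty contingency table")
    _, p = stats.fisher_exact(table, alternative="two-sided")
    if min(a, b, c, d) > 0:
        orr = (a * d) / (b * c)
        se_log_or = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
        z = stats.norm.ppf(0.975)
        or_ci = (float(np.exp(np.log(orr) - z * se_log_or)),
                 float(np.exp(np.log(orr) + z * se_log_or)))
    else:
        orr = float(_cmle_odds_ratio(table).statistic)
        ci = _cmle_odds_ratio(table).confidence_interval(0.95)
        or_ci = (float(ci.low), float(ci.high))
    p_sup = a / (a + b) if a + b else np.nan
    p_no = c / (c + d) if c + d else np.nan
    rs = p_sup / p_no if p_no else np.inf
    if min(a, c) > 0 and a + b > 0 and c + d > 0:
        se_log_rs = np.sqrt(max(1 / a - 1 / (a + b) + 1 / c - 1 / (c + d), 0.0))
        z = stats.norm.ppf(0.975)
        rs_ci = (float(np.exp(np.log(rs) - z * se_log_rs)),
                 float(np.exp(np.log(rs) + z * se_log_rs)))
    else:
        rs_ci = (0.0, np.inf)
    return EnrichmentResult(stratum, a, b, c, d, float(orr), float(rs), float(p),
                            or_ci, rs_ci)


def fisher_enrichment(ti: pd.DataFrame, stratum: str = "support") -> EnrichmentResult:
    """Enrichment of a genetic-evidence stratum in approval over a T-I table
    with columns ``approved`` and the stratum flag."""
    for c in ("approved", stratum):
        if c not in ti.columns:
            raise ValueError(f"T-I table missing column {c}")
    s = ti[stratum].astype(bool)
    appr = ti["approved"].astype(bool)
    a = int((s & appr).sum())
    b = int((s & ~appr).sum())
    c_ = int((~s & appr).sum())
    d = int((~s & ~appr).sum())
    return enrichment_from_table(a, b, c_, d, stratum=stratum)


def bootstrap_or_ci(
    a: int, b: int, c: int, d: int, n_boot: int = 200,
    rng: np.random.Generator | None = None, conf: float = 0.95,
) -> tuple[float, float]:
    """Percentile bootstrap CI of the sample OR by multinomial resampling of
    the 2x2 table (zero cells get a 0.5 continuity adjustment per resample)."""
    rng = rng or np.random.default_rng(0)
    n = a + b + c + d
    probs = np.array([a, b, c, d]) / n
    draws = rng.multinomial(n, probs, size=n_boot).astype(float)
    draws[draws == 0] = 0.5
    ors = (draws[:, 0] * draws[:, 3]) / (draws[:, 1] * draws[:, 2])
    lo, hi = np.quantile(ors, [(1 - conf) / 2, 1 - (1 - conf) / 2])
    return float(lo), float(hi)


# --------------------------------------------------------------------------- #
# stratified logistic comparison                                              #
# --------------------------------------------------------------------------- #


def compare_strata_logistic(
    ti: pd.DataFrame, stratum_a: str, stratum_b: str
) -> dict[str, float]:
    """Logistic approval ~ flagA + flagB; t-test on the coefficient
    difference."""
    for s in (stratum_a, stratum_b):
        if s not in ti.columns:
            raise ValueError(f"T-I table missing stratum column {s}")
        if ti[s].astype(bool).sum() == 0:
            raise ValueError(f"stratum {s} is empty")
    X = sm.add_constant(ti[[stratum_a, stratum_b]].astype(float).to_numpy())
    y = ti["approved"].astype(int).to_numpy()
    res = sm.Logit(y, X).fit(disp=0, maxiter=200)
    b1, b2 = res.params[1], res.params[2]
    cov = res.cov_params()
    var_diff = cov[1, 1] + cov[2, 2] - 2 * cov[1, 2]
    t = (b1 - b2) / np.sqrt(var_diff)
    dof = len(y) - X.shape[1]
    p = 2 * stats.t.sf(abs(t), dof)
    return {"coef_a": float(b1), "coef_b": float(b2), "t": float(t), "p": float(p),
            "or_a": float(np.exp(b1)), "or_b": float(np.exp(b2))}


def compare_many_strata(ti: pd.DataFrame, pairs: list[tuple[str, str]]) -> pd.DataFrame:
    rows = []
    for a, b in pairs:
        r = compare_strata_logistic(ti, a, b)
        rows.append({"stratum_a": a, "stratum_b": b, **r})
    out = pd.DataFrame(rows)
    out["q"] = bh_adjust(out["p"].to_numpy())
    return out


# --------------------------------------------------------------------------- #
# non-linear pleiotropy model                                                 #
# --------------------------------------------------------------------------- #


def _lrt(ll0: float, ll1: float, df: int) -> float:
    return float(stats.chi2.sf(2 * (ll1 - ll0), df))


def nonlinear_pleiotropy_model(
    ti: pd.DataFrame,
    count_col: str = "unique_diseases",
    n_boot: int = 200,
    seed: int = 0,
    lowess_frac: float = 0.6,
) -> dict:
    """Nested logistic models of approval on genetic support and the
    log-pleiotropy shape, with LRTs, bootstrap bands and a LOWESS curve.

    Models: baseline (support only), linear (+ log(count+1)), quadratic
    (+ log(count+1)^2).  Prediction bands use the 2.5th/97.5th percentiles of
    the quadratic model's predictions over 200 seeded resamples.
    """
    if ti.empty:
        raise ValueError("empty T-I table")
    counts = ti[count_col].astype(float).to_numpy()
    if np.any(counts < 1):
        raise ValueError(f"{count_col} must be >= 1")
    y = ti["approved"].astype(int).to_numpy()
    s = ti["support"].astype(float).to_numpy()
    ll = np.log(counts + 1.0)

    def _design(lvl: int, s_, ll_):
        cols = [s_]
        if lvl >= 1:
            cols.append(ll_)
        if lvl >= 2:
            cols.append(ll_**2)
        return sm.add_constant(np.column_stack(cols))

    fits = [sm.Logit(y, _design(k, s, ll)).fit(disp=0, maxiter=200) for k in range(3)]
    p_linear = _lrt(fits[0].llf, fits[1].llf, 1)
    p_quadratic = _lrt(fits[1].llf, fits[2].llf, 1)
    grid = np.linspace(counts.min(), counts.max(), 50)
    ll_grid = np.log(grid + 1.0)
    Xg = sm.add_constant(
        np.column_stack([np.ones_like(grid), ll_grid, ll_grid**2]), has_constant="add"
    )
    pred = fits[2].predict(Xg)
    rng = np.random.default_rng(seed)
    n = len(y)
    if n_boot > 0:
        boot_preds = np.empty((n_boot, len(grid)))
        for i in range(n_boot):
            idx = rng.integers(n, size=n)
            try:
                f = sm.Logit(y[idx], _design(2, s[idx], ll[idx])).fit(disp=0, maxiter=200)
                boot_preds[i] = f.predict(Xg)
            except Exception:
                boot_preds[i] = np.nan
        lo, hi = np.nanpercentile(boot_preds, [2.5, 97.5], axis=0)
    else:  # bands skipped
        lo = hi = np.full(len(grid), np.nan)
    lowess = sm.nonparametric.lowess(y, counts, frac=lowess_frac, xvals=grid)
    return {
        "loglik": [float(f.llf) for f in fits],
        "p_linear_vs_baseline": p_linear,
        "p_quadratic_vs_linear": p_quadratic,
        "coefficients": np.asarray(fits[2].params, dtype=float),
        "grid": grid, "predicted": np.asarray(pred), "band_lo": lo, "band_hi": hi,
        "lowess": np.asarray(lowess),
    }


# --------------------------------------------------------------------------- #
# phase transitions                                                           #
# --------------------------------------------------------------------------- #


def assign_pleiotropy_group(ta_count: int) -> str:
    for name, lo, hi in PLEIOTROPY_GROUPS:
        if ta_count >= lo and (hi is None or ta_count <= hi):
            return name
    return "low"


def phase_transitions(ti: pd.DataFrame, group_col: str = "ta_count") -> pd.DataFrame:
    """P(II|I), P(III|II), P(approval|III) per pleiotropy group with Wilson
    95% intervals; empty groups are omitted."""
    df = ti.copy()
    df["group"] = df[group_col].astype(int).map(assign_pleiotropy_group)
    rows = []
    for group, grp in df.groupby("group"):
        mp = grp["max_phase"].astype(int)
        for name, num, den in (
            ("II|I", (mp >= 2).sum(), len(grp)),
            ("III|II", (mp >= 3).sum(), (mp >= 2).sum()),
            ("approval|III", (mp >= 4).sum(), (mp >= 3).sum()),
        ):
            if den == 0:
                continue
            lo, hi = wilson_interval(int(num), int(den))
            rows.append({"group": group, "transition": name, "k": int(num),
                         "n": int(den), "p": num / den, "wilson_lo": lo, "wilson_hi": hi})
    return pd.DataFrame(rows)


def phase_transition_tests(trans: pd.DataFrame) -> pd.DataFrame:
    """Pairwise two-proportion z-tests between groups per transition, BH-corrected."""
    from statsmodels.stats.proportion import proportions_ztest

    rows = []
    for t, grp in trans.groupby("transition"):
        recs = grp.to_dict("records")
        for i in range(len(recs)):
            for j in range(i + 1, len(recs)):
                a, b = recs[i], recs[j]
                _, p = proportions_ztest([a["k"], b["k"]], [a["n"], b["n"]])
                rows.append({"transition": t, "group_a": a["group"],
                             "group_b": b["group"], "p": float(p)})
    out = pd.DataFrame(rows)
    if not out.empty:
        out["q"] = bh_adjust(out["p"].to_numpy())
    return out
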