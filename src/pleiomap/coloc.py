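"""Colocalisation of credible sets: overlaps, CLPP, posterior H4, direction.

Two quantifications are applied to every pair of 95% credible sets sharing at
least one variant:

* CLPP -- sum over shared variants of the product of the two posterior
  inclusion probabilities (significant at >= 0.01);
* the five-hypothesis posterior (H0 no signal, H1/H2 one trait only, H3 two
  distinct causal variants, H4 one shared causal variant) computed from
  per-variant Wakefield approximate Bayes factors under single-causal-variant
  configuration enumeration (significant at H4 >= 0.8).

Effect-direction concordance compares the signs of shared-variant effects
after harmonising the two sets to a common effect allele.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .harmonise import CredibleSet

CLPP_SIGNIFICANT = 0.01
H4_SIGNIFICANT = 0.8
MOLQTL_TYPES = {"eqtl", "pqtl", "sqtl", "tuqtl"}


@dataclass
class ColocResult:
    left_cs_id: str
    right_cs_id: str
    n_shared_variants: int
    clpp: float
    h_posteriors: tuple[float, float, float, float, float] | None = None
    direction: str = "unknown"  # concordant | discordant | unknown
    pair_class: str = ""  # gwas-gwas | gwas-molqtl | molqtl-molqtl

    @property
    def significant(self) -> bool:
        h4 = self.h_posteriors[4] if self.h_posteriors is not None else 0.0
        return self.clpp >= CLPP_SIGNIFICANT or h4 >= H4_SIGNIFICANT


def find_overlaps(cs_list: list[CredibleSet]) -> list[tuple[CredibleSet, CredibleSet]]:
    """All unordered pairs of credible sets sharing at least one variant."""
    by_variant: dict[str, list[int]] = {}
    for i, cs in enumerate(cs_list):
        for v, _ in cs.members:
            by_variant.setdefault(v, []).append(i)
    pairs = set()
    for idxs in by_variant.values():
        for a, b in combinations(sorted(set(idxs)), 2):
            pairs.add((a, b))
    return [(cs_list[a], cs_list[b]) for a, b in sorted(pairs)]


def pair_class(cs_a: CredibleSet, cs_b: CredibleSet) -> str:
    a_mol = cs_a.study_type in MOLQTL_TYPES
    b_mol = cs_b.study_type in MOLQTL_TYPES
    if a_mol and b_mol:
        return "molqtl-molqtl"
    if a_mol or b_mol:
        return "gwas-molqtl"
    return "gwas-gwas"


def clpp(cs_a: CredibleSet, cs_b: CredibleSet) -> float:
    """Colocalisation posterior probability: sum over shared variants of
    PIP_A(v) * PIP_B(v).  Symmetric; 0 when the sets are disjoint."""
    pips_a = dict(cs_a.members)
    return float(sum(p * pips_a[v] for v, p in cs_b.members if v in pips_a))


# --------------------------------------------------------------------------- #
# posterior H4                                                                #
# --------------------------------------------------------------------------- #


def wakefield_labf(beta: np.ndarray, se: np.ndarray, prior_sd: float) -> np.ndarray:
    """Log approximate Bayes factor per variant (normal prior on the effect)."""
    beta = np.asarray(beta, dtype=float)
    v = np.asarray(se, dtype=float) ** 2
    if np.any(v <= 0):
        raise ValueError("standard errors must be positive")
    w = prior_sd**2
    z2 = beta**2 / v
    return 0.5 * (np.log(v / (v + w)) + z2 * w / (v + w))


def coloc_h4(
    stats_a: pd.DataFrame,
    stats_b: pd.DataFrame,
    p1: float = 1e-4,
    p2: float = 1e-4,
    p12: float = 1e-5,
    prior_sd_a: float = 0.15,
    prior_sd_b: float = 0.15,
) -> tuple[float, float, float, float, float] | None:
    """Posterior probabilities (H0..H4) over the union region.

    ``stats_a``/``stats_b``: per-variant tables with columns variant_id, beta,
    se.  Regions with fewer than two variants in the union are unassessable
    and return None.
    """
    a = stats_a.set_index("variant_id")
    b = stats_b.set_index("variant_id")
    union = sorted(set(a.index) | set(b.index))
    if len(union) < 2:
        return None
    # absent variants contribute no evidence (lABF 0 under the null)
    labf_a = pd.Series(0.0, index=union)
    labf_b = pd.Series(0.0, index=union)
    labf_a.loc[a.index] = wakefield_labf(a["beta"].to_numpy(), a["se"].to_numpy(), prior_sd_a)
    labf_b.loc[b.index] = wakefield_labf(b["beta"].to_numpy(), b["se"].to_numpy(), prior_sd_b)
    la, lb = labf_a.to_numpy(), labf_b.to_numpy()
    # single-causal-variant configuration sums, in log space
    l1 = logsumexp(la)
    l2 = logsumexp(lb)
    lsum = logsumexp(la + lb)  # both causal at the same variant
    # H3: two distinct causal variants = sum_i sum_{j != i} ABF_a[i] ABF_b[j]
    l3_all = l1 + l2
    l3 = l3_all + np.log1p(-np.exp(min(lsum - l3_all, -1e-12)))
    logs = np.array([
        0.0,
        np.log(p1) + l1,
        np.log(p2) + l2,
        np.log(p1) + np.log(p2) + l3,
        np.log(p12) + lsum,
    ])
    post = np.exp(logs - logsumexp(logs))
    return tuple(float(x) for x in post / post.sum())


# --------------------------------------------------------------------------- #
# direction                                                                   #
# --------------------------------------------------------------------------- #

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def _is_strand_ambiguous(ea: str, oa: str) -> bool:
    return _COMPLEMENT.get(ea) == oa


def harmonised_sign(
    beta_a: float, ea_a: str, oa_a: str,
    beta_b: float, ea_b: str, oa_b: str,
    maf: float | None = None,
) -> float | None:
    """Sign product of the two effects on a common effect-allele frame.

    Returns +1 (concordant), -1 (discordant) or None (unusable: missing sign,
    allele mismatch, or strand-ambiguous A/T / C/G pair at MAF > 0.4).
    """
    if not np.isfinite(beta_a) or not np.isfinite(beta_b) or beta_a == 0 or beta_b == 0:
        return None
    if _is_strand_ambiguous(ea_a, oa_a) and maf is not None and maf > 0.4:
        return None
    if (ea_a, oa_a) == (ea_b, oa_b):
        flip = 1.0
    elif (ea_a, oa_a) == (oa_b, ea_b):
        flip = -1.0
    else:
        return None
    return float(np.sign(beta_a) * np.sign(flip * beta_b))


def coloc_direction(
    cs_a: CredibleSet,
    cs_b: CredibleSet,
    variant_effects: pd.DataFrame,
) -> str:
    """'concordant' / 'discordant' / 'unknown' from shared-variant effects.

    ``variant_effects``: columns cs_id, variant_id, beta, effect_allele,
    other_allele and optionally maf.  Any unusable sign among the shared
    variants makes the call 'unknown'; otherwise the PIP-weighted sign of the
    shared evidence decides.
    """
    ve = variant_effects.set_index(["cs_id", "variant_id"])
    shared = [v for v, _ in cs_a.members if any(v == w for w, _ in cs_b.members)]
    if not shared:
        return "unknown"
    total = 0.0
    for v in shared:
        try:
            ra = ve.loc[(cs_a.cs_id, v)]
            rb = ve.loc[(cs_b.cs_id, v)]
        except KeyError:
            return "unknown"
        maf = float(ra["maf"]) if "maf" in ra.index and pd.notna(ra["maf"]) else None
        s = harmonised_sign(
            float(ra["beta"]), str(ra["effect_allele"]), str(ra["other_allele"]),
            float(rb["beta"]), str(rb["effect_allele"]), str(rb["other_allele"]),
            maf=maf,
        )
        if s is None:
            return "unknown"
        total += cs_a.pip_of(v) * cs_b.pip_of(v) * s
    if total > 0:
        return "concordant"
    if total < 0:
        return "discordant"
    return "unknown"


# --------------------------------------------------------------------------- #
# batch driver                                                                #
# --------------------------------------------------------------------------- #


def colocalise_all(
    cs_list: list[CredibleSet],
    variant_effects: pd.DataFrame | None = None,
) -> list[ColocResult]:
    """CLPP for every overlapping pair; direction where effects are given."""
    results = []
    for cs_a, cs_b in find_overlaps(cs_list):
        shared = {v for v, _ in cs_a.members} & {v for v, _ in cs_b.members}
        direction = "unknown"
        if variant_effects is not None:
            direction = coloc_direction(cs_a, cs_b, variant_effects)
        results.append(
            ColocResult(
                left_cs_id=cs_a.cs_id, right_cs_id=cs_b.cs_id,
                n_shared_variants=len(shared), clpp=clpp(cs_a, cs_b),
                direction=direction, pair_class=pair_class(cs_a, cs_b),
            )
        )
    return results


def coloc_results_frame(results: list[ColocResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        h = r.h_posteriors or (np.nan,) * 5
        rows.append(
            {"left_cs_id": r.left_cs_id, "right_cs_id": r.right_cs_id,
             "n_shared": r.n_shared_variants, "clpp": r.clpp,
             "h0": h[0], "h1": h[1], "h2": h[2], "h3": h[3], "h4": h[4],
             "direction": r.direction, "pair_class": r.pair_class,
             "significant": r.significant}
        )
    return pd.DataFrame(rows)
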