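"""Study/credible-set harmonisation.

Annotates lead variants with the major-ancestry MAF, re-estimates effect sizes
and standard errors from Z-scores, computes detection power, resolves the most
severe variant consequence, and applies the qualification, replication,
representative-credible-set and therapeutic-area rules.

Effect rescaling follows the standard summary-statistic identities

    SE_logit = 1 / sqrt(2 n f (1-f) K (1-K))     (binary traits)
    SE_lm    = 1 / sqrt(2 n f (1-f))             (quantitative traits)
    beta_resc = SE * Z,   |Z| = sqrt(chi2_1 quantile at 1-p)

where n is the study sample size, f the major-ancestry MAF and K the case
proportion.  Detection power uses a non-central chi-square with

    NCP = maxBeta^2 * maxEffectiveN * 2 * maxMAF * (1 - maxMAF) / 11

i.e. the maximal observed effect scaled down by an order of magnitude on the
chi-square scale, against the genome-wide significance quantile.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import ndtri_exp

GWS_P = 1e-8
CONSEQUENCE_ORDER = ("PAV", "promoter", "enhancer", "intragenic", "intergenic")

# Documented default priority ordering of the 23 therapeutic areas.  Oncology
# outranks organ-system categories (e.g. 'ovarian cancer' maps to the cancer
# TA rather than the reproductive-system TA); 'measurement' is never assigned;
# 'other' is the fallback for traits reaching no TA root.
DEFAULT_TA_HIERARCHY: tuple[str, ...] = (
    "cell proliferation disorder",
    "infectious disease",
    "pregnancy or perinatal disease",
    "congenital disease",
    "genetic, familial or congenital disease",
    "psychiatric disorder",
    "nervous system disease",
    "cardiovascular disease",
    "respiratory or thoracic disease",
    "gastrointestinal disease",
    "pancreas disease",
    "hematologic disease",
    "immune system disease",
    "endocrine system disease",
    "nutritional or metabolic disease",
    "urinary system disease",
    "reproductive system or breast disease",
    "musculoskeletal or connective tissue disease",
    "integumentary system disease",
    "eye disease",
    "ear disease",
    "injury, poisoning or other complication",
    "other",
)


@dataclass
class StudyRecord:
    study_id: str
    study_type: str  # disease | measurement | eqtl | pqtl | sqtl | tuqtl
    trait_id: str
    n: int
    n_cases: int | None = None
    ancestry_composition: dict[str, float] = field(default_factory=lambda: {"NFE": 1.0})
    year: int = 2020
    cohort: str = ""
    publication: str = ""
    trait_category: str = ""  # e.g. 'protein_measurement', 'microbiome_measurement'

    @property
    def is_quantitative(self) -> bool:
        return self.study_type != "disease"

    def validate(self) -> None:
        tot = sum(self.ancestry_composition.values())
        if self.ancestry_composition and abs(tot - 1.0) > 1e-6:
            raise ValueError(f"ancestry proportions sum to {tot}, not 1")
        if self.study_type == "disease":
            if self.n_cases is None:
                raise ValueError(f"disease study {self.study_id} lacks n_cases")
            if self.n_cases > self.n:
                raise ValueError(f"study {self.study_id}: n_cases > n")


@dataclass
class CredibleSet:
    cs_id: str
    study_id: str
    lead_variant: str
    members: list[tuple[str, float]]  # (variant_id, PIP) in any order
    method: str = "ingested"  # susie | pics | ingested
    lead_p: float = np.nan
    beta_sign: str = "unknown"  # '+', '-', 'unknown'
    region: tuple[str, int, int] | None = None
    qualified: bool = False
    replicated: bool = False
    study_type: str = "disease"
    trait_id: str = ""
    lead_beta: float = np.nan

    def pip_of(self, variant_id: str) -> float:
        for v, p in self.members:
            if v == variant_id:
                return p
        return 0.0

    def validate(self) -> None:
        pips = np.array([p for _, p in self.members])
        if np.any(pips < 0) or np.any(pips > 1):
            raise ValueError(f"{self.cs_id}: PIP outside [0, 1]")
        s = pips.sum()
        if not (0.95 <= s <= 1 + 1e-9):
            raise ValueError(f"{self.cs_id}: PIP sum {s} outside [0.95, 1]")
        lead_pip = self.pip_of(self.lead_variant)
        if lead_pip < pips.max() - 1e-12:
            raise ValueError(f"{self.cs_id}: lead variant does not have maximal PIP")


# --------------------------------------------------------------------------- #
# MAF annotation                                                              #
# --------------------------------------------------------------------------- #


def major_ancestry(composition: dict[str, float]) -> str:
    """Population with the largest sample proportion; exact ties prefer NFE,
    else the first population listed."""
    if not composition:
        raise ValueError("empty ancestry composition")
    pops = list(composition)
    if len(pops) == 1:
        return pops[0]
    best = max(composition.values())
    tied = [p for p in pops if composition[p] == best]
    if len(tied) > 1 and "NFE" in tied:
        return "NFE"
    return tied[0]


def annotate_major_ancestry_maf(
    study: StudyRecord, variant_id: str, freq_table: pd.DataFrame
) -> float | None:
    """Major-ancestry MAF = min(EAF, 1 - EAF); None marks a failed annotation
    (variant absent, or no frequency defined for the major population)."""
    pop = major_ancestry(study.ancestry_composition)
    col = f"eaf_{pop}"
    if col not in freq_table.columns:
        return None
    tab = freq_table.set_index("variant_id") if "variant_id" in freq_table.columns else freq_table
    if variant_id not in tab.index:
        return None
    eaf = tab.loc[variant_id, col]
    if pd.isna(eaf):
        return None
    eaf = float(eaf)
    return min(eaf, 1.0 - eaf)


# --------------------------------------------------------------------------- #
# effect rescaling and power                                                  #
# --------------------------------------------------------------------------- #


def z_from_p(p: float | None = None, log10_p: float | None = None) -> float:
    """|Z| from a two-sided p-value; accepts log10(p) for underflowing values."""
    if log10_p is None:
        if p is None:
            raise ValueError("provide p or log10_p")
        if not 0.0 < p <= 1.0:
            raise ValueError("p must lie in (0, 1]; use log10_p for underflow")
        log10_p = np.log10(p)
    # p = 2 * Phi(-|Z|)  =>  |Z| = -Phi^-1(p/2), evaluated in log space
    log_half_p = log10_p * np.log(10.0) - np.log(2.0)
    return float(-ndtri_exp(log_half_p))


@dataclass
class RescaledEffect:
    variant_id: str
    study_id: str
    f: float
    z: float
    se_hat: float
    beta_resc: float
    direction_usable: bool


def rescale_effect(
    p: float | None,
    sign: str,
    n: float,
    f: float,
    K: float | None = None,
    trait_type: str = "quantitative",
    log10_p: float | None = None,
) -> tuple[float, float]:
    """(se_hat, beta_resc) re-estimated from the p-value and sample size.

    ``sign`` in {'+', '-', 'unknown'}; with an unknown sign the magnitude is
    returned (callers must flag the record direction-unusable).
    """
    if not 0.0 < f <= 0.5:
        raise ValueError(f"MAF f={f} outside (0, 0.5]")
    if n <= 0:
        raise ValueError("n must be positive")
    if trait_type == "binary":
        if K is None or not 0.0 < K < 1.0:
            raise ValueError("binary trait requires case proportion K in (0, 1)")
        se = 1.0 / np.sqrt(2.0 * n * f * (1.0 - f) * K * (1.0 - K))
    else:
        se = 1.0 / np.sqrt(2.0 * n * f * (1.0 - f))
    z = z_from_p(p=p, log10_p=log10_p)
    beta = se * z
    if sign == "-":
        beta = -beta
    return float(se), float(beta)


def effective_sample_size(n: float, n_cases: float | None = None) -> float:
    """4/(1/cases + 1/controls) for binary designs, n for quantitative."""
    if n_cases is None:
        return float(n)
    n_controls = n - n_cases
    if n_cases <= 0 or n_controls <= 0:
        raise ValueError("binary study needs positive cases and controls")
    return 4.0 / (1.0 / n_cases + 1.0 / n_controls)


def compute_power(max_beta: float, max_eff_n: float, max_maf: float,
                  gws_p: float = GWS_P) -> float:
    """Expected power to detect the variant's associations, assuming effects an
    order of magnitude below its maximal observed effect (the /11 rescale)."""
    if max_eff_n <= 0:
        raise ValueError("max_eff_n must be positive")
    if not 0.0 < max_maf <= 0.5:
        raise ValueError(f"max_maf={max_maf} outside (0, 0.5]")
    ncp = max_beta**2 * max_eff_n * 2.0 * max_maf * (1.0 - max_maf) / 11.0
    q = stats.chi2.isf(gws_p, df=1)
    power = float(stats.ncx2.sf(q, df=1, nc=ncp))
    return min(max(power, gws_p), 1.0)


# --------------------------------------------------------------------------- #
# consequence resolution                                                      #
# --------------------------------------------------------------------------- #


def resolve_most_severe(categories) -> str:
    """Single category by the fixed severity order PAV > promoter > enhancer >
    intragenic > intergenic."""
    cats = set(categories)
    if not cats:
        raise ValueError("no candidate categories")
    unknown = cats - set(CONSEQUENCE_ORDER)
    if unknown:
        raise ValueError(f"unknown consequence categories: {sorted(unknown)}")
    for c in CONSEQUENCE_ORDER:
        if c in cats:
            return c
    raise AssertionError("unreachable")


def filter_lead_variants_for_consequence_analysis(cs_table: pd.DataFrame) -> pd.DataFrame:
    """Keep replicated, qualified credible sets with lead PIP >= 0.5, and per
    (lead variant, trait) the single representative set with the largest
    |rescaled beta|."""
    required = {"cs_id", "lead_variant", "trait_id", "lead_pip", "qualified",
                "replicated", "beta_resc"}
    missing = required - set(cs_table.columns)
    if missing:
        raise ValueError(f"cs table missing columns {sorted(missing)}")
    keep = cs_table[
        cs_table["qualified"] & cs_table["replicated"] & (cs_table["lead_pip"] >= 0.5)
    ].copy()
    keep["_abs_beta"] = keep["beta_resc"].abs()
    keep = (
        keep.sort_values(["_abs_beta", "cs_id"], ascending=[False, True])
        .drop_duplicates(subset=["lead_variant", "trait_id"], keep="first")
        .drop(columns="_abs_beta")
    )
    return keep.sort_index()


# --------------------------------------------------------------------------- #
# replication and qualification                                               #
# --------------------------------------------------------------------------- #


def flag_replication(cs_table: pd.DataFrame, studies: dict[str, StudyRecord]) -> pd.Series:
    """GWAS credible set: replicated iff its (lead variant, trait) recurs in a
    different cohort/biobank, publication or ancestry group.  molQTL credible
    set: replicated iff its (lead variant, gene) pair recurs at least twice."""
    molqtl_types = {"eqtl", "pqtl", "sqtl", "tuqtl"}
    ancestry = {
        sid: major_ancestry(st.ancestry_composition) for sid, st in studies.items()
    }

    def _context(row):
        st = studies[row["study_id"]]
        return (st.cohort, st.publication, ancestry[row["study_id"]])

    out = pd.Series(False, index=cs_table.index)
    is_mol = cs_table["study_type"].isin(molqtl_types)
    gwas = cs_table[~is_mol]
    for _, grp in gwas.groupby(["lead_variant", "trait_id"]):
        if len(grp) >= 2:
            contexts = {_context(r) for _, r in grp.iterrows()}
            if len(contexts) >= 2:
                out.loc[grp.index] = True
    mol = cs_table[is_mol]
    key_col = "gene_id" if "gene_id" in mol.columns else "trait_id"
    for _, grp in mol.groupby(["lead_variant", key_col]):
        if len(grp) >= 2:
            out.loc[grp.index] = True
    return out


def qualify_studies(studies: dict[str, StudyRecord]) -> dict[str, bool]:
    """Disease studies: binary, n > 1000 (strict), in-study prevalence > 0.1%.
    Measurement studies: quantitative, excluding protein/microbiome traits."""
    out = {}
    for sid, st in studies.items():
        if st.study_type == "disease":
            ok = (
                st.n_cases is not None
                and st.n > 1000
                and st.n_cases / st.n > 0.001
            )
        elif st.study_type == "measurement":
            ok = st.trait_category not in ("protein_measurement", "microbiome_measurement")
        else:
            ok = True  # molQTL studies are not subject to these rules
        out[sid] = bool(ok)
    return out


def qualify_credible_sets(
    cs_table: pd.DataFrame,
    study_qualified: dict[str, bool],
    has_significant_coloc: pd.Series | None = None,
    has_pav: pd.Series | None = None,
) -> pd.Series:
    """Minor allele count >= 20 and |rescaled beta| < 3 (strict); rare leads
    (MAF < 1%) additionally need molQTL colocalisation, a PAV in the set, or
    replication.  Requires columns maf, beta_resc, n, replicated."""
    required = {"study_id", "maf", "beta_resc", "n", "replicated"}
    missing = required - set(cs_table.columns)
    if missing:
        raise ValueError(f"cs table missing columns {sorted(missing)}")
    if has_significant_coloc is None:
        has_significant_coloc = pd.Series(False, index=cs_table.index)
    if has_pav is None:
        has_pav = pd.Series(False, index=cs_table.index)
    study_ok = cs_table["study_id"].map(study_qualified).fillna(False).astype(bool)
    mac = 2.0 * cs_table["n"] * cs_table["maf"]
    base = study_ok & (mac >= 20) & (cs_table["beta_resc"].abs() < 3.0)
    rare = cs_table["maf"] < 0.01
    rare_ok = has_significant_coloc | has_pav | cs_table["replicated"].astype(bool)
    return base & (~rare | rare_ok)


# --------------------------------------------------------------------------- #
# therapeutic areas                                                           #
# --------------------------------------------------------------------------- #


def ancestors(term: str, parent_edges: dict[str, list[str]]) -> set[str]:
    """All ancestors of ``term`` (term included) by BFS over child->parent edges."""
    seen, frontier = {term}, [term]
    while frontier:
        nxt = []
        for t in frontier:
            for p in parent_edges.get(t, []):
                if p not in seen:
                    seen.add(p)
                    nxt.append(p)
        frontier = nxt
    return seen


def assign_therapeutic_area(
    trait_id: str,
    parent_edges: dict[str, list[str]],
    ta_hierarchy: tuple[str, ...] | list[str] = DEFAULT_TA_HIERARCHY,
) -> str:
    """Highest-priority therapeutic area among the TA roots reachable from the
    trait by ancestor traversal; 'measurement' is dropped; none -> 'other'."""
    prio = {ta: i for i, ta in enumerate(ta_hierarchy)}
    reach = [t for t in ancestors(trait_id, parent_edges) if t in prio and t != "measurement"]
    if not reach:
        return "other"
    return min(reach, key=lambda t: prio[t])
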