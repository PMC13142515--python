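"""Synthetic cohort generator with planted ground truth.

Emulates, at desk scale, the inputs of a large post-GWAS analysis: LD-blocked
genomes, study summary statistics with an inverse MAF-|beta| coupling, GWAS and
molQTL credible sets that colocalise by construction, variant/gene annotations,
and a target-indication clinical pipeline whose approval odds depend on genetic
support and a log-shaped pleiotropy term.

Every operation draws from a named child stream of the root seed, so identical
configurations reproduce identical outputs and stages can be re-run in
isolation.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy import stats
from scipy.optimize import brentq

from ._utils import make_variant_id, named_rng

GWS_P = 1e-8
POPULATIONS = ("NFE", "AFR", "EAS", "CSA", "FIN")
CONSEQUENCE_CATEGORIES = ("PAV", "promoter", "enhancer", "intragenic", "intergenic")


# --------------------------------------------------------------------------- #
# configuration                                                               #
# --------------------------------------------------------------------------- #


@dataclass
class TIPlan:
    """Clinical-pipeline plan: per-phase transition probabilities and the
    planted approval model ``logit P(approved) = base + b_support*support +
    b_lin*log(uD+1) + b_quad*log(uD+1)^2``.

    Phase-advance defaults follow the marginal phase distribution of a large
    curated clinical corpus (~83.5% of Phase I programmes reach Phase II, ~46%
    of those reach Phase III); the support log-odds bonus defaults to log(3.6).
    """

    n_records: int = 10_000
    base_logodds: float = -2.3
    b_support: float = float(np.log(3.6))
    b_lin: float = 0.0
    b_quad: float = 0.0
    q12: float = 0.835
    q23: float = 0.46
    support_rate: float = 0.2
    oncology_rate: float = 0.0

    def validate(self) -> None:
        for name in ("q12", "q23", "support_rate", "oncology_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"TIPlan.{name}={v} outside [0, 1]")
        if self.n_records <= 0:
            raise ValueError("TIPlan.n_records must be positive")


@dataclass
class PlantedGene:
    gene_id: str
    diseases: tuple[str, ...]
    tas: tuple[str, ...]


@dataclass
class SimulationConfig:
    seed: int = 0
    n_ld_blocks: int = 8
    block_size_bp: int = 1_000_000
    variants_per_block: int = 60
    genes_per_block: int = 3
    n_disease_studies: int = 42
    n_measurement_studies: int = 8
    n_molqtl_studies: int = 20
    # beta-distribution shape of the MAF spectrum (free parameter; documented,
    # not calibrated -- no quantitative spectrum is specified for the cohorts
    # this stands in for)
    maf_spectrum: tuple[float, float] = (0.6, 1.2)
    # exponent alpha in |beta| = beta_scale * [2 f (1-f)]^-alpha.  alpha=0.5
    # makes detection power MAF-independent while keeping the inverse
    # MAF-|beta| relationship.
    effect_coupling: float = 0.5
    beta_scale: float = 0.045
    ld_rho: float = 0.92
    discordance_rate: float = 0.1
    molqtl_coloc_fraction: float = 0.8
    pav_rates: tuple[tuple[float, float], ...] = (
        (0.01, 0.30),
        (0.05, 0.18),
        (0.10, 0.10),
        (0.50, 0.05),
    )
    n_tissues: int = 12
    pleiotropy_plan: list[PlantedGene] = field(default_factory=list)
    ti_plan: TIPlan = field(default_factory=TIPlan)

    def validate(self) -> None:
        for name in (
            "n_ld_blocks",
            "block_size_bp",
            "variants_per_block",
            "genes_per_block",
            "n_disease_studies",
            "n_measurement_studies",
            "n_molqtl_studies",
            "n_tissues",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"SimulationConfig.{name} must be positive")
        for maf_hi, rate in self.pav_rates:
            if not (0.0 <= rate <= 1.0 and 0.0 < maf_hi <= 0.5):
                raise ValueError("pav_rates entries must be (maf<=0.5, rate in [0,1])")
        if not 0.0 <= self.molqtl_coloc_fraction <= 1.0:
            raise ValueError("molqtl_coloc_fraction outside [0, 1]")
        if not 0.0 < self.ld_rho < 1.0:
            raise ValueError("ld_rho must lie in (0, 1)")
        self.ti_plan.validate()

    # -- YAML round trip ---------------------------------------------------- #

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["pleiotropy_plan"] = [
            {"gene_id": g.gene_id, "diseases": list(g.diseases), "tas": list(g.tas)}
            for g in self.pleiotropy_plan
        ]
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        d["ti_plan"] = TIPlan(**d.get("ti_plan", {}))
        d["pleiotropy_plan"] = [
            PlantedGene(g["gene_id"], tuple(g["diseases"]), tuple(g["tas"]))
            for g in d.get("pleiotropy_plan", [])
        ]
        d["maf_spectrum"] = tuple(d["maf_spectrum"])
        d["pav_rates"] = tuple(tuple(x) for x in d["pav_rates"])
        cfg = cls(**d)
        cfg.validate()
        return cfg


def default_pleiotropy_plan(n_genes: int, rng: np.random.Generator) -> list[PlantedGene]:
    """Planted gene->disease map with a spread of pleiotropy levels.

    Each disease belongs to exactly one therapeutic area (TA); a gene's planted
    TA set is the union over its diseases, so true gPS >= true TA count.
    """
    n_tas = 7
    diseases_per_ta = 3
    disease_pool = [f"EFO:D{t:02d}{i:02d}" for t in range(n_tas) for i in range(diseases_per_ta)]
    ta_of = {d: f"TA{int(d[5:7]):02d}" for d in disease_pool}
    sizes = [1, 1, 1, 2, 2, 3, 3, 4, 5, 6, 7, 8]
    plan = []
    for g in range(n_genes):
        k = sizes[g % len(sizes)]
        chosen = tuple(
            str(x) for x in rng.choice(disease_pool, size=min(k, len(disease_pool)), replace=False)
        )
        plan.append(PlantedGene(f"G{g + 1:04d}", chosen, tuple(sorted({ta_of[d] for d in chosen}))))
    return plan


def default_config(seed: int = 0) -> SimulationConfig:
    cfg = SimulationConfig(seed=seed)
    rng = named_rng(seed, "pleiotropy_plan")
    cfg.pleiotropy_plan = default_pleiotropy_plan(cfg.n_ld_blocks * cfg.genes_per_block, rng)
    cfg.validate()
    return cfg


# --------------------------------------------------------------------------- #
# genome                                                                      #
# --------------------------------------------------------------------------- #


@dataclass
class Genome:
    variants: pd.DataFrame  # variant_id, chrom, pos, ref, alt, maf, block
    ld: dict[int, pd.DataFrame]  # per-block signed-r matrix keyed by variant id
    genes: pd.DataFrame  # gene_id, chrom, tss, start, end, block, protein_coding

    def block_of(self, variant_id: str) -> int:
        return int(self.variants.set_index("variant_id").loc[variant_id, "block"])


def _nearest_psd(r: np.ndarray) -> np.ndarray:
    """Clip negative eigenvalues and restore the unit diagonal."""
    w, v = np.linalg.eigh(r)
    w = np.clip(w, 1e-10, None)
    r2 = (v * w) @ v.T
    d = np.sqrt(np.diag(r2))
    r2 = r2 / np.outer(d, d)
    return (r2 + r2.T) / 2.0


def _ar1_ld(n: int, rho: float, rng: np.random.Generator, max_retries: int = 3) -> np.ndarray:
    """Signed AR(1)-style LD: r_ij = s_i s_j rho^|i-j| (PSD by construction;
    non-PSD draws are projected / re-drawn with bounded retries)."""
    for _ in range(max_retries):
        signs = rng.choice([-1.0, 1.0], size=n)
        base = rho ** np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
        r = np.outer(signs, signs) * base
        np.fill_diagonal(r, 1.0)
        if np.linalg.eigvalsh(r).min() >= -1e-8:
            return r
        r = _nearest_psd(r)
        if np.linalg.eigvalsh(r).min() >= -1e-8:
            return r
    raise RuntimeError("failed to construct a positive semi-definite LD matrix")


def simulate_ld_genome(config: SimulationConfig) -> Genome:
    config.validate()
    rng = named_rng(config.seed, "genome")
    rows, ld, gene_rows = [], {}, []
    per_chrom_next = {}
    gid = 0
    for b in range(config.n_ld_blocks):
        chrom = str((b % 4) + 1)
        start = per_chrom_next.get(chrom, 1)
        per_chrom_next[chrom] = start + config.block_size_bp
        m = config.variants_per_block
        offsets = np.sort(rng.choice(config.block_size_bp - 1, size=m, replace=False))
        a, bshape = config.maf_spectrum
        mafs = np.clip(rng.beta(a, bshape, size=m) * 0.5, 0.002, 0.5)
        ids = []
        for pos_off, maf in zip(offsets, mafs):
            ref, alt = rng.choice(list("ACGT"), size=2, replace=False)
            pos = start + int(pos_off)
            vid = make_variant_id(chrom, pos, ref, alt)
            rows.append(
                {"variant_id": vid, "chrom": chrom, "pos": pos, "ref": ref, "alt": alt,
                 "maf": float(maf), "block": b}
            )
            ids.append(vid)
        r = _ar1_ld(m, config.ld_rho, rng)
        ld[b] = pd.DataFrame(r, index=ids, columns=ids)
        # genes at evenly spaced TSS positions inside the block
        for k in range(config.genes_per_block):
            tss = start + int((k + 0.5) / config.genes_per_block * config.block_size_bp)
            gid += 1
            gene_rows.append(
                {"gene_id": f"G{gid:04d}", "chrom": chrom, "tss": tss,
                 "start": tss - 20_000, "end": tss + 20_000, "block": b,
                 "protein_coding": bool(rng.random() > 0.1)}
            )
    return Genome(pd.DataFrame(rows), ld, pd.DataFrame(gene_rows))


# --------------------------------------------------------------------------- #
# power / planted effect sizes                                                #
# --------------------------------------------------------------------------- #


def gws_power(ncp: float, gws_p: float = GWS_P) -> float:
    """P(chi2_1(ncp) exceeds the (1 - gws_p) central chi2_1 quantile)."""
    q = stats.chi2.isf(gws_p, df=1)
    return float(stats.ncx2.sf(q, df=1, nc=ncp))


def beta_for_power(power: float, n: float, f: float, gws_p: float = GWS_P) -> float:
    """|beta| of a quantitative-trait variant detected genome-wide significant
    with the given probability at sample size ``n`` and MAF ``f``."""
    if not 0.0 < power < 1.0:
        raise ValueError("power must lie in (0, 1)")
    ncp = brentq(lambda x: gws_power(x, gws_p) - power, 1e-9, 1e4)
    se = 1.0 / np.sqrt(2.0 * n * f * (1.0 - f))
    return float(np.sqrt(ncp) * se)


def planted_beta(f: float, config: SimulationConfig) -> float:
    """Planted |beta| under the inverse MAF coupling |beta| ~ [2f(1-f)]^-alpha."""
    return float(config.beta_scale * (2.0 * f * (1.0 - f)) ** (-config.effect_coupling))


# --------------------------------------------------------------------------- #
# studies and summary statistics                                              #
# --------------------------------------------------------------------------- #


@dataclass
class StudySpec:
    study_id: str
    study_type: str  # disease | measurement | eqtl | pqtl | sqtl
    trait_id: str
    n: int
    n_cases: int | None = None
    signals: list[tuple[str, float]] = field(default_factory=list)  # (variant_id, beta)
    cohort: str = "COHORT1"
    publication: str = "PMID1"
    ancestry: str = "NFE"
    year: int = 2020
    gene_id: str | None = None  # molQTL affected gene


@dataclass
class TruthTable:
    """Planted ground truth: one row per (gene, disease) signal, plus the
    planted per-gene disease/TA sets and the clinical-model coefficients."""

    signals: pd.DataFrame  # gene_id, trait_id, ta, causal_variant, beta, has_molqtl, qtl_type
    gene_diseases: dict[str, set[str]]
    gene_tas: dict[str, set[str]]
    ti_coefficients: dict[str, float]

    def true_gps(self, gene_id: str) -> int:
        return len(self.gene_diseases[gene_id])

    def check_closure(self, genome: Genome) -> None:
        known_v = set(genome.variants["variant_id"])
        known_g = set(genome.genes["gene_id"])
        bad_v = set(self.signals["causal_variant"]) - known_v
        bad_g = set(self.signals["gene_id"]) - known_g
        if bad_v or bad_g:
            raise ValueError(f"dangling truth-table references: variants={bad_v} genes={bad_g}")


def build_truth(genome: Genome, config: SimulationConfig) -> TruthTable:
    """Assign each planted gene one causal variant (close to its TSS) shared
    across all of its planted diseases: variant-level pleiotropy by design."""
    rng = named_rng(config.seed, "truth")
    vtab = genome.variants
    rows = []
    gene_diseases: dict[str, set[str]] = {}
    gene_tas: dict[str, set[str]] = {}
    gidx = genome.genes.set_index("gene_id")
    for pg in config.pleiotropy_plan:
        if pg.gene_id not in gidx.index:
            raise KeyError(f"pleiotropy_plan references unknown gene {pg.gene_id}")
        block = int(gidx.loc[pg.gene_id, "block"])
        tss = int(gidx.loc[pg.gene_id, "tss"])
        cand = vtab[vtab["block"] == block]
        causal = cand.iloc[(cand["pos"] - tss).abs().argsort().iloc[0]]
        base_sign = rng.choice([-1.0, 1.0])
        gene_diseases[pg.gene_id] = set(pg.diseases)
        gene_tas[pg.gene_id] = set(pg.tas)
        for disease in pg.diseases:
            sign = base_sign * (-1.0 if rng.random() < config.discordance_rate else 1.0)
            beta = sign * planted_beta(float(causal["maf"]), config)
            rows.append(
                {"gene_id": pg.gene_id, "trait_id": disease,
                 "ta": _ta_of_disease(disease, pg), "causal_variant": causal["variant_id"],
                 "beta": float(beta),
                 "has_molqtl": bool(rng.random() < config.molqtl_coloc_fraction),
                 "qtl_type": str(rng.choice(["eqtl", "pqtl", "sqtl"], p=[0.6, 0.25, 0.15]))}
            )
    truth = TruthTable(
        signals=pd.DataFrame(rows),
        gene_diseases=gene_diseases,
        gene_tas=gene_tas,
        ti_coefficients={
            "base": config.ti_plan.base_logodds,
            "b_support": config.ti_plan.b_support,
            "b_lin": config.ti_plan.b_lin,
            "b_quad": config.ti_plan.b_quad,
        },
    )
    truth.check_closure(genome)
    return truth


def _ta_of_disease(disease: str, pg: PlantedGene) -> str:
    # disease ids encode their TA (default plan convention); fall back to first TA
    if disease.startswith("EFO:D") and len(disease) >= 9:
        return f"TA{disease[5:7]}"
    return pg.tas[0] if pg.tas else "other"


def build_studies(genome: Genome, truth: TruthTable, config: SimulationConfig) -> list[StudySpec]:
    """Disease studies cycle over planted diseases; measurement and molQTL
    studies carry their own signals.  Sample sizes span 10^4 - 10^5.3."""
    rng = named_rng(config.seed, "studies")
    studies: list[StudySpec] = []
    diseases = sorted(truth.signals["trait_id"].unique())
    by_disease = truth.signals.groupby("trait_id")
    cohorts = ["UKB", "FINNGEN", "MVP", "BBJ"]
    for i in range(config.n_disease_studies):
        disease = diseases[i % len(diseases)]
        n = int(10 ** rng.uniform(4.2, 5.3))
        n_cases = int(n * rng.uniform(0.05, 0.4))
        sig = [(r["causal_variant"], r["beta"]) for _, r in by_disease.get_group(disease).iterrows()]
        studies.append(
            StudySpec(
                study_id=f"GWAS{i + 1:04d}", study_type="disease", trait_id=disease,
                n=n, n_cases=n_cases, signals=sig,
                cohort=cohorts[i % len(cohorts)],
                publication=f"PMID{1000 + i}",
                ancestry=str(rng.choice(["NFE", "NFE", "NFE", "EAS", "AFR"])),
                year=int(rng.integers(2010, 2025)),
            )
        )
    for i in range(config.n_measurement_studies):
        vid = str(rng.choice(genome.variants["variant_id"]))
        f = float(genome.variants.set_index("variant_id").loc[vid, "maf"])
        studies.append(
            StudySpec(
                study_id=f"MEAS{i + 1:04d}", study_type="measurement",
                trait_id=f"EFO:M{i + 1:03d}", n=int(10 ** rng.uniform(4.2, 5.3)),
                signals=[(vid, rng.choice([-1, 1]) * planted_beta(f, config))],
                cohort="UKB", publication=f"PMID{2000 + i}", year=int(rng.integers(2010, 2025)),
            )
        )
    return studies


def simulate_study_sumstats(
    genome: Genome, study: StudySpec, config: SimulationConfig
) -> pd.DataFrame:
    """Marginal z-scores under the RSS model z ~ N(R z_causal, R) per LD block."""
    rng = named_rng(config.seed, f"sumstats:{study.study_id}")
    vtab = genome.variants
    vindex = vtab.set_index("variant_id")
    for vid, _ in study.signals:
        if vid not in vindex.index:
            raise KeyError(f"study {study.study_id} references unknown variant id {vid}")
    n = study.n
    out = []
    signal_by_block: dict[int, list[tuple[str, float]]] = {}
    for vid, beta in study.signals:
        signal_by_block.setdefault(int(vindex.loc[vid, "block"]), []).append((vid, beta))
    for b, ldm in genome.ld.items():
        ids = list(ldm.index)
        sub = vindex.loc[ids]
        f = sub["maf"].to_numpy()
        se = 1.0 / np.sqrt(2.0 * n * f * (1.0 - f))
        z_causal = np.zeros(len(ids))
        for vid, beta in signal_by_block.get(b, []):
            j = ids.index(vid)
            z_causal[j] = beta / se[j]
        r = ldm.to_numpy()
        chol = np.linalg.cholesky(r + 1e-8 * np.eye(len(ids)))
        z = r @ z_causal + chol @ rng.standard_normal(len(ids))
        p = stats.chi2.sf(z**2, df=1)
        out.append(
            pd.DataFrame(
                {"variant_id": ids, "chromosome": sub["chrom"].to_numpy(),
                 "base_pair_location": sub["pos"].to_numpy(),
                 "effect_allele": sub["alt"].to_numpy(), "other_allele": sub["ref"].to_numpy(),
                 "beta": z * se, "standard_error": se, "p_value": p,
                 "n": n, "n_cases": study.n_cases if study.n_cases is not None else pd.NA}
            )
        )
    df = pd.concat(out, ignore_index=True)
    return df.sort_values(["chromosome", "base_pair_location"], ignore_index=True)


# --------------------------------------------------------------------------- #
# credible sets                                                               #
# --------------------------------------------------------------------------- #


def _draw_credible_set(
    rng: np.random.Generator, genome: Genome, causal_variant: str, r2_min: float = 0.5
) -> list[tuple[str, float]]:
    """Members and PIPs of a 95% credible set centred on a causal variant.

    The causal variant receives PIP in [0.5, 0.9]; the remaining mass is
    spread over its r^2 >= 0.5 proxies proportionally to r^2, then the set is
    truncated at cumulative PIP >= 0.95 (so the PIP sum lies in [0.95, 1]).
    """
    block = genome.block_of(causal_variant)
    ldm = genome.ld[block]
    r2 = ldm[causal_variant] ** 2
    proxies = [v for v in ldm.index if v != causal_variant and r2[v] >= r2_min]
    lead_pip = float(rng.uniform(0.55, 0.9))
    members = [(causal_variant, lead_pip)]
    if proxies:
        w = np.array([r2[v] for v in proxies]) * rng.dirichlet(np.ones(len(proxies)) * 2.0)
        w = w / w.sum() * (1.0 - lead_pip)
        members += list(zip(proxies, w.astype(float)))
    members.sort(key=lambda t: -t[1])
    kept, cum = [], 0.0
    for vid, pip in members:
        kept.append((vid, pip))
        cum += pip
        if cum >= 0.95:
            break
    if cum < 0.95:  # no proxies and lead_pip < 0.95: renormalise the singleton
        kept = [(causal_variant, 1.0)]
    return kept


def simulate_gwas_cs(
    genome: Genome, studies: list[StudySpec], config: SimulationConfig
) -> list[dict]:
    """Generator-side GWAS credible sets (one per planted study signal)."""
    rng = named_rng(config.seed, "gwas_cs")
    vindex = genome.variants.set_index("variant_id")
    out = []
    k = 0
    for st in studies:
        if st.study_type not in ("disease", "measurement"):
            continue
        for vid, beta in st.signals:
            f = float(vindex.loc[vid, "maf"])
            se = 1.0 / np.sqrt(2.0 * st.n * f * (1.0 - f))
            z_obs = beta / se + rng.standard_normal()
            lead_p = float(stats.chi2.sf(z_obs**2, df=1))
            members = _draw_credible_set(rng, genome, vid)
            chrom = str(vindex.loc[vid, "chrom"])
            pos = [int(vindex.loc[m, "pos"]) for m, _ in members]
            k += 1
            out.append(
                {"cs_id": f"CS{k:05d}", "study_id": st.study_id, "study_type": st.study_type,
                 "trait_id": st.trait_id, "lead_variant": vid,
                 "members": members, "method": "pics", "lead_p": lead_p,
                 "beta_sign": "+" if beta > 0 else "-", "lead_beta": float(z_obs * se),
                 "region": (chrom, min(pos), max(pos))}
            )
    return out


def simulate_molqtl_cs(genome: Genome, truth: TruthTable, config: SimulationConfig) -> list[dict]:
    """molQTL credible sets; planted colocalising pairs share the GWAS causal
    variant as their highest-PIP member."""
    rng = named_rng(config.seed, "molqtl_cs")
    out = []
    k = 0
    planted = truth.signals[truth.signals["has_molqtl"]].drop_duplicates("gene_id")
    for _, row in planted.iterrows():
        members = _draw_credible_set(rng, genome, row["causal_variant"])
        k += 1
        out.append(
            {"cs_id": f"QCS{k:05d}", "study_id": f"QTL{k:04d}",
             "study_type": row["qtl_type"], "trait_id": f"{row['gene_id']}:{row['qtl_type']}",
             "gene_id": row["gene_id"], "lead_variant": row["causal_variant"],
             "members": members, "method": "susie",
             "lead_p": float(10.0 ** -rng.uniform(5, 20)),
             "beta_sign": str(rng.choice(["+", "-"])),
             "region": _region_of(genome, members)}
        )
    # background molQTL CSs at random variants (no planted GWAS partner)
    n_bg = max(0, config.n_molqtl_studies - len(out))
    genes = genome.genes["gene_id"].tolist()
    for _ in range(n_bg):
        vid = str(rng.choice(genome.variants["variant_id"]))
        members = _draw_credible_set(rng, genome, vid)
        k += 1
        out.append(
            {"cs_id": f"QCS{k:05d}", "study_id": f"QTL{k:04d}", "study_type": "eqtl",
             "trait_id": "bg", "gene_id": str(rng.choice(genes)), "lead_variant": vid,
             "members": members, "method": "susie",
             "lead_p": float(10.0 ** -rng.uniform(4, 12)),
             "beta_sign": str(rng.choice(["+", "-"])), "region": _region_of(genome, members)}
        )
    return out


def _region_of(genome: Genome, members: list[tuple[str, float]]) -> tuple[str, int, int]:
    vindex = genome.variants.set_index("variant_id")
    pos = [int(vindex.loc[m, "pos"]) for m, _ in members]
    chrom = str(vindex.loc[members[0][0], "chrom"])
    return (chrom, min(pos), max(pos))


# --------------------------------------------------------------------------- #
# annotations                                                                 #
# --------------------------------------------------------------------------- #


def pav_rate_for_maf(maf: float, pav_rates: tuple[tuple[float, float], ...]) -> float:
    for hi, rate in sorted(pav_rates):
        if maf <= hi:
            return rate
    return sorted(pav_rates)[-1][1]


def simulate_annotations(
    genome: Genome, config: SimulationConfig
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """(variant annotations, gene covariates, gene x tissue expression).

    Variant consequence categories are drawn with a configurable per-MAF-bin
    PAV rate; pathogenicity scores are Beta-distributed (high for PAVs).
    Per-population EAFs jitter the simulated MAF.
    """
    rng = named_rng(config.seed, "annotations")
    vtab = genome.variants
    gidx = genome.genes
    rows = []
    non_pav = np.array(["promoter", "enhancer", "intragenic", "intergenic"])
    non_pav_p = np.array([0.06, 0.12, 0.50, 0.32])
    for _, v in vtab.iterrows():
        genes_b = gidx[gidx["block"] == v["block"]]
        nearest = genes_b.iloc[(genes_b["tss"] - v["pos"]).abs().argsort().iloc[0]]
        if rng.random() < pav_rate_for_maf(float(v["maf"]), config.pav_rates):
            cat, patho = "PAV", float(rng.beta(6, 2))
        else:
            cat, patho = str(rng.choice(non_pav, p=non_pav_p)), float(rng.beta(1.2, 8))
        eafs = {
            f"eaf_{p}": float(np.clip(v["maf"] + rng.normal(0, 0.02), 5e-4, 0.9995))
            for p in POPULATIONS
        }
        rows.append({"variant_id": v["variant_id"], "gene_id": nearest["gene_id"],
                     "category": cat, "pathogenicity": patho, **eafs})
    var_ann = pd.DataFrame(rows)

    n_genes = len(gidx)
    lof = rng.uniform(0, 1, n_genes)
    mis = np.clip(0.6 * lof + 0.4 * rng.uniform(0, 1, n_genes), 0, 1)
    gene_cov = pd.DataFrame(
        {"gene_id": gidx["gene_id"].to_numpy(), "lof_constraint": lof,
         "missense_constraint": mis,
         "pathway_count": 1 + rng.poisson(5, n_genes),
         "gene_length": np.exp(rng.normal(10.5, 0.8, n_genes)).astype(int)}
    )

    tissues = [f"T{t + 1:02d}" for t in range(config.n_tissues)]
    expr = np.exp(rng.normal(2.0, 0.3, size=(n_genes, config.n_tissues)))
    specific = rng.random(n_genes) < 0.25
    for i in np.flatnonzero(specific):
        expr[i, rng.integers(config.n_tissues)] *= 10.0
    expr_df = pd.DataFrame(expr, index=gidx["gene_id"].to_numpy(), columns=tissues)
    return var_ann, gene_cov, expr_df


# --------------------------------------------------------------------------- #
# clinical pipeline                                                           #
# --------------------------------------------------------------------------- #


def draw_ti_targets(plan: TIPlan, rng: np.random.Generator,
                    gene_table: pd.DataFrame | None = None) -> pd.DataFrame:
    """One row per target-indication record: support flag and pleiotropy count.

    When a gene table with planted pleiotropy is given, targets are sampled
    from it (unique diseases = planted gPS); otherwise pleiotropy counts are
    drawn from 1 + a heavy-tailed lognormal, mirroring observed gPS skew.
    """
    plan.validate()
    n = plan.n_records
    support = (rng.random(n) < plan.support_rate).astype(int)
    if gene_table is not None and len(gene_table):
        idx = rng.integers(len(gene_table), size=n)
        genes = gene_table["gene_id"].to_numpy()[idx]
        ud = gene_table["unique_diseases"].to_numpy()[idx]
    else:
        genes = np.array([f"G{i % 500 + 1:04d}" for i in range(n)])
        ud = np.minimum(1 + np.floor(np.exp(rng.normal(0.4, 1.0, n))).astype(int), 120)
    return pd.DataFrame(
        {"target_id": genes, "indication_id": [f"EFO:I{i:05d}" for i in range(n)],
         "support": support, "unique_diseases": ud,
         "oncology": (rng.random(n) < plan.oncology_rate).astype(int)}
    )


def simulate_ti_pipeline(
    targets: pd.DataFrame, plan: TIPlan, rng: np.random.Generator
) -> pd.DataFrame:
    """Target-indication records with planted approval model.

    Approval is Bernoulli with
    ``logit p = base + b_support*support + b_lin*log(uD+1) + b_quad*log(uD+1)^2``;
    non-approved records get their maximum phase from sequential Bernoulli
    phase transitions (I->II, II->III).
    """
    plan.validate()
    for col in ("target_id", "support", "unique_diseases"):
        if col not in targets.columns:
            raise ValueError(f"targets table missing column {col}")
    ll = np.log(targets["unique_diseases"].to_numpy() + 1.0)
    eta = plan.base_logodds + plan.b_support * targets["support"].to_numpy() \
        + plan.b_lin * ll + plan.b_quad * ll**2
    p_app = 1.0 / (1.0 + np.exp(-eta))
    if np.any(~np.isfinite(p_app)) or np.any(p_app < 0) or np.any(p_app > 1):
        raise ValueError("approval probabilities outside [0, 1] after link inversion")
    n = len(targets)
    approved = rng.random(n) < p_app
    reach2 = rng.random(n) < plan.q12
    reach3 = reach2 & (rng.random(n) < plan.q23)
    max_phase = np.where(approved, 4, np.where(reach3, 3, np.where(reach2, 2, 1)))
    out = targets.copy()
    out["max_phase"] = max_phase.astype(int)
    out["approved"] = approved.astype(int)
    return out


# --------------------------------------------------------------------------- #
# one-call cohort                                                             #
# --------------------------------------------------------------------------- #


@dataclass
class SyntheticCohort:
    config: SimulationConfig
    genome: Genome
    truth: TruthTable
    studies: list[StudySpec]
    sumstats: dict[str, pd.DataFrame]
    gwas_cs: list[dict]
    molqtl_cs: list[dict]
    variant_annotations: pd.DataFrame
    gene_covariates: pd.DataFrame
    expression: pd.DataFrame
    ti_records: pd.DataFrame


def simulate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Run every generator stage off the single root seed."""
    config.validate()
    if not config.pleiotropy_plan:
        rng = named_rng(config.seed, "pleiotropy_plan")
        config.pleiotropy_plan = default_pleiotropy_plan(
            config.n_ld_blocks * config.genes_per_block, rng
        )
    genome = simulate_ld_genome(config)
    truth = build_truth(genome, config)
    studies = build_studies(genome, truth, config)
    sumstats = {st.study_id: simulate_study_sumstats(genome, st, config) for st in studies}
    gwas_cs = simulate_gwas_cs(genome, studies, config)
    molqtl_cs = simulate_molqtl_cs(genome, truth, config)
    var_ann, gene_cov, expr = simulate_annotations(genome, config)
    rng_ti = named_rng(config.seed, "ti")
    gene_support = pd.DataFrame(
        {"gene_id": list(truth.gene_diseases),
         "unique_diseases": [len(v) for v in truth.gene_diseases.values()]}
    )
    targets = draw_ti_targets(config.ti_plan, rng_ti, gene_table=gene_support)
    # indication choice keyed to the planted support flag: supported records
    # get one of the target gene's planted diseases, unsupported records get a
    # disease outside it, so recomputing support from evidence matches truth
    all_diseases = sorted({d for s in truth.gene_diseases.values() for d in s})
    indications = []
    for gid, sup in zip(targets["target_id"], targets["support"]):
        own = sorted(truth.gene_diseases[gid])
        other = [d for d in all_diseases if d not in own]
        pool = own if (sup == 1 or not other) else other
        indications.append(str(pool[rng_ti.integers(len(pool))]))
    targets["indication_id"] = indications
    targets["support"] = [
        int(i in truth.gene_diseases[g]) for g, i in zip(targets["target_id"], indications)
    ]
    ti = simulate_ti_pipeline(targets, config.ti_plan, rng_ti)
    return SyntheticCohort(
        config=config, genome=genome, truth=truth, studies=studies, sumstats=sumstats,
        gwas_cs=gwas_cs, molqtl_cs=molqtl_cs, variant_annotations=var_ann,
        gene_covariates=gene_cov, expression=expr, ti_records=ti,
    )
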