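"""Plain-text readers and writers for the pipeline's interchange formats:
GWAS-SSF-style TSV summary statistics, credible sets as JSON Lines, and LD
matrices as TSV."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .harmonise import CredibleSet

SSF_COLUMNS = [
    "variant_id", "chromosome", "base_pair_location", "effect_allele",
    "other_allele", "beta", "standard_error", "p_value", "n", "n_cases",
]


def write_sumstats(df: pd.DataFrame, path) -> None:
    missing = [c for c in SSF_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"summary statistics missing columns {missing}")
    df[SSF_COLUMNS].to_csv(path, sep="\t", index=False)


def read_sumstats(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chromosome": str})
    missing = [c for c in SSF_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return df


def write_credible_sets(cs_list: list[CredibleSet], path) -> None:
    with open(path, "w") as fh:
        for cs in cs_list:
            rec = {
                "cs_id": cs.cs_id, "study_id": cs.study_id,
                "lead_variant": cs.lead_variant,
                "members": [[v, float(p)] for v, p in cs.members],
                "method": cs.method, "lead_p": float(cs.lead_p),
                "beta_sign": cs.beta_sign,
                "region": list(cs.region) if cs.region else None,
                "qualified": cs.qualified, "replicated": cs.replicated,
                "study_type": cs.study_type, "trait_id": cs.trait_id,
                "lead_beta": None if not np.isfinite(cs.lead_beta) else float(cs.lead_beta),
            }
            fh.write(json.dumps(rec) + "\n")


def read_credible_sets(path) -> list[CredibleSet]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            d = json.loads(line)
            out.append(
                CredibleSet(
                    cs_id=d["cs_id"], study_id=d["study_id"],
                    lead_variant=d["lead_variant"],
                    members=[(v, float(p)) for v, p in d["members"]],
                    method=d.get("method", "ingested"),
                    lead_p=float(d.get("lead_p", np.nan)),
                    beta_sign=d.get("beta_sign", "unknown"),
                    region=tuple(d["region"]) if d.get("region") else None,
                    qualified=bool(d.get("qualified", False)),
                    replicated=bool(d.get("replicated", False)),
                    study_type=d.get("study_type", "disease"),
                    trait_id=d.get("trait_id", ""),
                    lead_beta=float(d["lead_beta"]) if d.get("lead_beta") is not None
                    else np.nan,
                )
            )
    return out


def write_ld(ld: pd.DataFrame, path) -> None:
    ld.to_csv(path, sep="\t")


def read_ld(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_ontology_edges(parent_edges: dict[str, list[str]], path) -> None:
    with open(path, "w") as fh:
        fh.write("child\tparent\n")
        for child, parents in sorted(parent_edges.items()):
            for p in parents:
                fh.write(f"{child}\t{p}\n")


def read_ontology_edges(path) -> dict[str, list[str]]:
    df = pd.read_csv(path, sep="\t")
    out: dict[str, list[str]] = {}
    for _, r in df.iterrows():
        out.setdefault(str(r["child"]), []).append(str(r["parent"]))
    return out


def validate_inputs(paths: dict[str, str | Path]) -> list[dict]:
    """Per-file format diagnostics (column presence, PIP ranges, monotone
    positions) with line numbers; empty report means well-formed inputs."""
    report: list[dict] = []
    for kind, path in paths.items():
        path = Path(path)
        if not path.exists():
            report.append({"file": str(path), "level": "error", "line": None,
                           "message": "file not found"})
            continue
        if kind == "sumstats":
            try:
                df = read_sumstats(path)
            except ValueError as e:
                report.append({"file": str(path), "level": "error", "line": 1,
                               "message": str(e)})
                continue
            for chrom, grp in df.groupby("chromosome"):
                pos = grp["base_pair_location"].to_numpy()
                if np.any(np.diff(pos) < 0):
                    report.append({"file": str(path), "level": "warning", "line": None,
                                   "message": f"unsorted positions on chromosome {chrom}"})
        elif kind == "credible_sets":
            with open(path) as fh:
                for i, line in enumerate(fh, start=1):
                    if not line.strip():
                        continue
                    try:
                        d = json.loads(line)
                    except json.JSONDecodeError:
                        report.append({"file": str(path), "level": "error", "line": i,
                                       "message": "invalid JSON"})
                        continue
                    for v, p in d.get("members", []):
                        if not 0.0 <= p <= 1.0:
                            report.append(
                                {"file": str(path), "level": "error", "line": i,
                                 "message": f"PIP {p} for {v} outside [0, 1]"}
                            )
    return report
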