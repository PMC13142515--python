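"""Shared helpers: seeded named random streams and variant-id handling.

All randomness in the package flows from a single root seed.  Each operation
draws from its own named child stream so that adding draws to one stage never
perturbs another (stage-level reproducibility).
"""

from __future__ import annotations

import hashlib

import numpy as np

VARIANT_ID_SEP = "_"


def named_rng(root_seed: int, name: str) -> np.random.Generator:
    """Generator for the child stream ``name`` derived from ``root_seed``.

    The stream key is a stable hash of the name, so streams are independent of
    call order and of each other.
    """
    digest = hashlib.sha256(name.encode("utf-8")).digest()
    key = int.from_bytes(digest[:4], "little")
    return np.random.default_rng(np.random.SeedSequence([int(root_seed) % (2**31), key]))


def make_variant_id(chrom: str | int, pos: int, ref: str, alt: str) -> str:
    """``chr_pos_ref_alt`` underscore-delimited id, e.g. ``19_44908684_T_C``."""
    return VARIANT_ID_SEP.join([str(chrom), str(int(pos)), ref, alt])


def parse_variant_id(variant_id: str) -> tuple[str, int, str, str]:
    chrom, pos, ref, alt = variant_id.split(VARIANT_ID_SEP)
    return chrom, int(pos), ref, alt


def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted q-values (thin wrapper, NaN-safe)."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(pvalues, dtype=float)
    q = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    if ok.sum():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q
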