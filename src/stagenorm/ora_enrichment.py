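"""Hypergeometric over-representation analysis with BH correction.

Each module's gene list is tested against every set of a GMT collection
(intersected with the reference universe first).  The p-value is the
hypergeometric upper tail P(X >= x) for drawing x set members in a
module of size n from a universe of N genes containing K set members.
Benjamini-Hochberg correction is applied within each module's family of
tested sets, mirroring a per-module enrichment run.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from stagenorm.io_formats import GeneSetCollection

ENRICHMENT_COLUMNS = [
    "module",
    "set_name",
    "overlap",
    "module_size",
    "set_size",
    "universe_size",
    "p_value",
    "q_value",
    "overlap_genes",
]


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order preserved."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def hypergeom_upper_tail(x: int, N: int, K: int, n: int) -> float:
    """P(X >= x) for X ~ Hypergeometric(N, K, n)."""
    return float(hypergeom.sf(x - 1, N, K, n))


def run_ora(
    module_genes: Iterable[str],
    universe: Iterable[str],
    sets: GeneSetCollection,
    min_overlap: int = 2,
    module_name: str = "module",
) -> pd.DataFrame:
    """Test one gene list against every set in the collection.

    Sets are intersected with the universe before testing; sets with
    overlap below ``min_overlap`` are excluded from the test family.
    Returns one row per tested set with hypergeometric p and BH q.
    """
    universe_list = list(dict.fromkeys(universe))
    if not universe_list:
        raise ValueError("empty reference universe")
    uni = set(universe_list)
    mod = [g for g in dict.fromkeys(module_genes)]
    outside = [g for g in mod if g not in uni]
    if outside:
        raise ValueError(f"module genes outside the universe: {outside[:5]}")
    N, n = len(uni), len(mod)
    mod_set = set(mod)

    rows = []
    for set_name in sets.names():
        members = [g for g in sets.members(set_name) if g in uni]
        K = len(members)
        if K == 0:
            continue
        overlap_genes = sorted(mod_set.intersection(members))
        x = len(overlap_genes)
        if x < min_overlap:
            continue
        rows.append(
            {
                "module": module_name,
                "set_name": set_name,
                "overlap": x,
                "module_size": n,
                "set_size": K,
                "universe_size": N,
                "p_value": hypergeom_upper_tail(x, N, K, n),
                "overlap_genes": ";".join(overlap_genes),
            }
        )
    df = pd.DataFrame(rows, columns=[c for c in ENRICHMENT_COLUMNS if c != "q_value"])
    df["q_value"] = bh_adjust(df["p_value"].to_numpy()) if len(df) else []
    return df[ENRICHMENT_COLUMNS]


def run_ora_per_module(
    module_genes: dict[str, list[str]],
    universe: Iterable[str],
    sets: GeneSetCollection,
    min_overlap: int = 2,
) -> pd.DataFrame:
    """ORA for every module, with BH applied within each module's family."""
    frames = [
        run_ora(genes, universe, sets, min_overlap=min_overlap, module_name=name)
        for name, genes in module_genes.items()
    ]
    if not frames:
        return pd.DataFrame(columns=ENRICHMENT_COLUMNS)
    return pd.concat(frames, ignore_index=True)
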