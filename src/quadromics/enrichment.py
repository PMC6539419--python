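"""KEGG-style pathway over-representation analysis.

For a differential set of size n (features carrying at least one pathway
annotation) against an annotated background of size N, a pathway with K
background members and k differential members is scored with the one-sided
hypergeometric upper tail P(X >= k) — equivalent to a one-sided Fisher's
exact test on the 2x2 table — followed by Benjamini–Hochberg adjustment.
The enrichment factor reported for plotting is (k/n)/(K/N).
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "hypergeom_upper_tail",
    "bh_fdr",
    "enrich_pathways",
    "co_mapped_pathways",
    "ENRICHMENT_COLUMNS",
]

ENRICHMENT_COLUMNS = [
    "pathway_id",
    "pathway_name",
    "k",
    "n",
    "K",
    "N",
    "p",
    "fdr",
    "enrichment_factor",
    "significant",
]


def hypergeom_upper_tail(k: int, n: int, K: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N population, K marked, n drawn).

    Computed through scipy's survival function (stable log-space internals).
    """
    if not (0 <= k <= min(n, K) and n <= N and K <= N and n >= 0 and K >= 0):
        raise ValueError(f"inconsistent counts k={k} n={n} K={K} N={N}")
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjustment, input order preserved."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def enrich_pathways(
    diff_set: Iterable[str],
    background: Iterable[str],
    pathway_map: Mapping[str, frozenset[str] | set[str]],
    pathway_names: Mapping[str, str] | None = None,
    fdr_threshold: float = 0.05,
    factor_definition: str = "relative",
) -> pd.DataFrame:
    """Pathway over-representation of ``diff_set`` within ``background``.

    The background is restricted to features with at least one pathway
    annotation (N); the differential set is restricted likewise (n).  Only
    pathways hit by at least one differential feature are reported, sorted
    by p ascending with ties broken by pathway id.

    ``factor_definition``: ``"relative"`` -> (k/n)/(K/N); ``"hit_ratio"`` -> k/K.
    """
    if factor_definition not in ("relative", "hit_ratio"):
        raise ValueError(f"unknown factor_definition {factor_definition!r}")
    background = set(background)
    diff_set = set(diff_set)
    stray = diff_set - background
    if stray:
        raise ValueError(f"differential features missing from background: {sorted(stray)[:5]}")
    annotated = {f for f in background if pathway_map.get(f)}
    if not annotated:
        raise ValueError("no background feature carries a pathway annotation")
    diff_annotated = diff_set & annotated
    N = len(annotated)
    n = len(diff_annotated)

    members: dict[str, set[str]] = {}
    for fid in annotated:
        for pid in pathway_map[fid]:
            members.setdefault(pid, set()).add(fid)

    rows = []
    for pid, feats in members.items():
        hits = feats & diff_annotated
        k = len(hits)
        if k == 0:
            continue
        K = len(feats)
        p = hypergeom_upper_tail(k, n, K, N)
        factor = (k / n) / (K / N) if factor_definition == "relative" else k / K
        rows.append(
            {
                "pathway_id": pid,
                "pathway_name": (pathway_names or {}).get(pid, ""),
                "k": k,
                "n": n,
                "K": K,
                "N": N,
                "p": p,
                "enrichment_factor": factor,
            }
        )
    out = pd.DataFrame(rows, columns=[c for c in ENRICHMENT_COLUMNS if c not in ("fdr", "significant")])
    if out.empty:
        out["fdr"] = []
        out["significant"] = []
        return out[ENRICHMENT_COLUMNS]
    out["fdr"] = bh_fdr(out["p"])
    out["significant"] = out["fdr"] < fdr_threshold
    out = out.sort_values(["p", "pathway_id"], kind="mergesort").reset_index(drop=True)
    return out[ENRICHMENT_COLUMNS]


def co_mapped_pathways(
    metabolite_results: pd.DataFrame, gene_results: pd.DataFrame
) -> pd.DataFrame:
    """Pathways hit by both the metabolite and the gene differential sets.

    Joins the two enrichment tables on pathway_id (suffixes ``_met`` /
    ``_gene``), keeping only pathways present in both (k >= 1 each side).
    """
    merged = metabolite_results.merge(
        gene_results, on="pathway_id", suffixes=("_met", "_gene"), how="inner"
    )
    return merged.sort_values("pathway_id", kind="mergesort").reset_index(drop=True)
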