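"""Gene–metabolite association: correlation, nine quadrants, signed networks.

Pairs of differential genes and metabolites are correlated (Pearson, on
log2 replicate profiles of the two compared stages by default, or on the
two stage means, which yields exactly ±1 for any non-degenerate pair),
classified into the nine quadrants of the (metabolite status, gene status)
3x3 grid, and assembled into a signed bipartite network keeping only pairs
with |PCC| above threshold (strict, default 0.8).

Quadrant map (metabolite status, gene status) -> quadrant:

    (up, down) -> 1        (up, unchanged) -> 2        (up, up) -> 3
    (unchanged, down) -> 4 (unchanged, unchanged) -> 5 (unchanged, up) -> 6
    (down, down) -> 7      (down, unchanged) -> 8      (down, up) -> 9

Quadrants 3 and 7 hold co-directional (positively correlated) pairs,
1 and 9 the discordant ones.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .data_io import AbundanceMatrix, ComparisonSpec

__all__ = [
    "AssociationPair",
    "QUADRANT_MAP",
    "pair_pcc",
    "quadrant_classify",
    "associate",
    "quadrant_table",
    "build_network",
    "network_summary",
    "export_network",
    "load_graphml",
]

logger = logging.getLogger(__name__)

_STATUSES = ("up", "unchanged", "down")
QUADRANT_MAP: dict[tuple[str, str], int] = {
    ("up", "down"): 1,
    ("up", "unchanged"): 2,
    ("up", "up"): 3,
    ("unchanged", "down"): 4,
    ("unchanged", "unchanged"): 5,
    ("unchanged", "up"): 6,
    ("down", "down"): 7,
    ("down", "unchanged"): 8,
    ("down", "up"): 9,
}


@dataclasses.dataclass(frozen=True)
class AssociationPair:
    """One gene–metabolite pair with its correlation and quadrant."""

    gene_id: str
    metabolite_id: str
    pcc: float
    gene_status: str = "unchanged"
    metabolite_status: str = "unchanged"
    gene_log2fc: float = float("nan")
    metabolite_log2fc: float = float("nan")

    @property
    def quadrant(self) -> int:
        return quadrant_classify(self.metabolite_status, self.gene_status)

    def passes_threshold(self, pcc_threshold: float = 0.8) -> bool:
        return abs(self.pcc) > pcc_threshold


def pair_pcc(
    gene_profile: Sequence[float],
    metabolite_profile: Sequence[float],
    mode: str = "replicates",
) -> float | None:
    """Pearson correlation of two matched profiles.

    ``replicates`` correlates the supplied points as-is (normally the
    replicate values of the two compared stages); ``stage_means`` requires
    exactly two points per profile, where any non-degenerate pair gives
    exactly +1 or -1.  Returns None when either profile has zero variance
    (pair excluded, reason logged).
    """
    g = np.asarray(gene_profile, dtype=float)
    m = np.asarray(metabolite_profile, dtype=float)
    if g.shape != m.shape or g.ndim != 1 or g.size < 2:
        raise ValueError("profiles must be matched 1-D vectors with >= 2 points")
    if mode == "stage_means":
        if g.size != 2:
            raise ValueError("stage_means mode requires exactly 2 points")
    elif mode != "replicates":
        raise ValueError(f"unknown mode {mode!r}")
    if g.std() == 0 or m.std() == 0:
        logger.info("pair excluded: zero-variance profile")
        return None
    if mode == "stage_means":
        # two points: sign of the product of the two deltas, exactly +/-1
        return 1.0 if (g[1] - g[0]) * (m[1] - m[0]) > 0 else -1.0
    r = np.corrcoef(g, m)[0, 1]
    return float(np.clip(r, -1.0, 1.0))


def quadrant_classify(metabolite_status: str, gene_status: str) -> int:
    """Map a (metabolite status, gene status) combination to quadrant 1–9."""
    key = (metabolite_status, gene_status)
    if key not in QUADRANT_MAP:
        raise ValueError(f"invalid status combination {key!r}")
    return QUADRANT_MAP[key]


def associate(
    genes: AbundanceMatrix,
    metabolites: AbundanceMatrix,
    cmp: ComparisonSpec,
    gene_status: pd.Series,
    metabolite_status: pd.Series,
    gene_log2fc: pd.Series | None = None,
    metabolite_log2fc: pd.Series | None = None,
    gene_ids: Iterable[str] | None = None,
    metabolite_ids: Iterable[str] | None = None,
    mode: str = "replicates",
) -> list[AssociationPair]:
    """Correlate every (gene, metabolite) combination over the contrast samples.

    Profiles are log2(x+1) values over the replicates of the two compared
    stages (``replicates`` mode) or the two stage means (``stage_means``).
    Pairs with an undefined correlation are excluded.
    """
    cmp.validate(genes.design)
    cmp.validate(metabolites.design)
    gids = list(gene_ids) if gene_ids is not None else list(gene_status.index)
    mids = list(metabolite_ids) if metabolite_ids is not None else list(metabolite_status.index)

    def profile(matrix: AbundanceMatrix, fid: str) -> np.ndarray:
        ref = matrix.stage_values(cmp.ref_stage).loc[fid].to_numpy(dtype=float)
        test = matrix.stage_values(cmp.test_stage).loc[fid].to_numpy(dtype=float)
        if mode == "stage_means":
            return np.log2(np.array([ref.mean(), test.mean()]) + 1.0)
        return np.log2(np.concatenate([ref, test]) + 1.0)

    pairs: list[AssociationPair] = []
    gene_profiles = {g: profile(genes, g) for g in gids}
    met_profiles = {m: profile(metabolites, m) for m in mids}
    for g in gids:
        for m in mids:
            r = pair_pcc(gene_profiles[g], met_profiles[m], mode=mode)
            if r is None:
                continue
            pairs.append(
                AssociationPair(
                    gene_id=g,
                    metabolite_id=m,
                    pcc=r,
                    gene_status=str(gene_status.get(g, "unchanged")),
                    metabolite_status=str(metabolite_status.get(m, "unchanged")),
                    gene_log2fc=float(gene_log2fc.get(g, np.nan)) if gene_log2fc is not None else float("nan"),
                    metabolite_log2fc=float(metabolite_log2fc.get(m, np.nan)) if metabolite_log2fc is not None else float("nan"),
                )
            )
    return pairs


def quadrant_table(pairs: Sequence[AssociationPair]) -> tuple[pd.Series, pd.DataFrame]:
    """Per-quadrant counts (1–9, summing to len(pairs)) and a plot-ready table."""
    counts = pd.Series(0, index=pd.RangeIndex(1, 10, name="quadrant"), name="count")
    rows = []
    for p in pairs:
        q = p.quadrant
        counts[q] += 1
        rows.append(
            {
                "gene_id": p.gene_id,
                "metabolite_id": p.metabolite_id,
                "gene_log2fc": p.gene_log2fc,
                "metabolite_log2fc": p.metabolite_log2fc,
                "pcc": p.pcc,
                "quadrant": q,
            }
        )
    table = pd.DataFrame(
        rows,
        columns=["gene_id", "metabolite_id", "gene_log2fc", "metabolite_log2fc", "pcc", "quadrant"],
    )
    return counts, table


def build_network(pairs: Iterable[AssociationPair], pcc_threshold: float = 0.8) -> nx.Graph:
    """Signed bipartite network of pairs with |PCC| strictly above threshold.

    Nodes carry ``kind`` (gene|metabolite); edges carry ``pcc`` and ``sign``
    (positive|negative).  Duplicate pairs collapse to one edge (set
    semantics), so construction is idempotent and order-independent.
    """
    net = nx.Graph()
    for p in pairs:
        if not p.passes_threshold(pcc_threshold):
            continue
        net.add_node(p.gene_id, kind="gene")
        net.add_node(p.metabolite_id, kind="metabolite")
        net.add_edge(
            p.gene_id,
            p.metabolite_id,
            pcc=float(p.pcc),
            sign="positive" if p.pcc > 0 else "negative",
        )
    return net


def network_summary(net: nx.Graph) -> dict:
    """Node/edge/sign totals and the per-node degree table."""
    signs = [d["sign"] for _, _, d in net.edges(data=True)]
    kinds = nx.get_node_attributes(net, "kind")
    degree = pd.DataFrame(
        [{"node_id": n, "kind": kinds.get(n, ""), "degree": d} for n, d in net.degree()],
        columns=["node_id", "kind", "degree"],
    ).sort_values(["degree", "node_id"], ascending=[False, True], kind="mergesort").reset_index(drop=True)
    return {
        "nodes": net.number_of_nodes(),
        "gene_nodes": sum(1 for k in kinds.values() if k == "gene"),
        "metabolite_nodes": sum(1 for k in kinds.values() if k == "metabolite"),
        "edges": net.number_of_edges(),
        "positive_edges": signs.count("positive"),
        "negative_edges": signs.count("negative"),
        "degree": degree,
    }


def export_network(net: nx.Graph, path: str | Path, format: str = "graphml") -> None:
    """Write the network as GraphML, SIF (interaction pos/neg) or an edge TSV."""
    path = Path(path)
    if format == "graphml":
        nx.write_graphml(net, path)
    elif format == "sif":
        kinds = nx.get_node_attributes(net, "kind")
        with open(path, "w", encoding="utf-8") as handle:
            for u, v, d in sorted(net.edges(data=True)):
                g, m = (u, v) if kinds.get(u) == "gene" else (v, u)
                tag = "pos" if d["sign"] == "positive" else "neg"
                handle.write(f"{g}\t{tag}\t{m}\n")
    elif format == "edge_tsv":
        kinds = nx.get_node_attributes(net, "kind")
        rows = []
        for u, v, d in sorted(net.edges(data=True)):
            g, m = (u, v) if kinds.get(u) == "gene" else (v, u)
            rows.append({"gene_id": g, "metabolite_id": m, "pcc": d["pcc"], "sign": d["sign"]})
        pd.DataFrame(rows, columns=["gene_id", "metabolite_id", "pcc", "sign"]).to_csv(
            path, sep="\t", index=False
        )
    else:
        raise ValueError(f"unknown format {format!r}")


def load_graphml(path: str | Path) -> nx.Graph:
    """Re-import a GraphML export (inverse of :func:`export_network`)."""
    net = nx.read_graphml(path)
    net.graph.pop("node_default", None)
    net.graph.pop("edge_default", None)
    return net
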