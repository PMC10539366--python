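"""Confidence-filtered PPI graph and MCODE-style molecular complex detection.

The PPI network is the subgraph induced on the query genes by edges whose
confidence score strictly exceeds a cutoff (default 0.9).  Complexes are
found with the Bader-Hogue MCODE scheme: each vertex is weighted by
k * density of the highest k-core of its closed neighborhood, complexes are
grown breadth-first from the heaviest unassigned seed, admitting neighbors
whose weight is at least (1 - node_score_cutoff) times the seed weight, and
a haircut removes members whose in-complex degree falls below the degree
cutoff.  Complexes are scored density x size; members of the top complex
are the hub genes.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import pandas as pd

from .errors import HubSelectionError, ParseError

DEFAULT_SCORE_CUTOFF = 0.9
DEFAULT_NODE_SCORE_CUTOFF = 0.2
DEFAULT_DEGREE_CUTOFF = 2


@dataclass(frozen=True)
class Complex:
    """A detected complex: member set, internal edge count, density, score."""

    members: tuple[str, ...]
    edge_count: int
    density: float
    score: float


def read_ppi_table(path: str | Path) -> pd.DataFrame:
    """Read a PPI edge TSV with columns a, b, score."""
    df = pd.read_csv(path, sep="\t", dtype={"a": str, "b": str})
    for col in ("a", "b", "score"):
        if col not in df.columns:
            raise ParseError(f"PPI table lacks column '{col}'")
    bad = df.index[(df["score"] < 0) | (df["score"] > 1) | df["score"].isna()]
    if len(bad):
        # +2: header line plus 1-based numbering
        raise ParseError("PPI score outside [0, 1]", int(bad[0]) + 2)
    return df


def build_ppin(
    edge_table: pd.DataFrame,
    query_genes: list[str],
    score_cutoff: float = DEFAULT_SCORE_CUTOFF,
) -> nx.Graph:
    """Induced PPI subgraph on ``query_genes`` keeping edges with score > cutoff.

    Self-loops and duplicate edges are dropped (highest score wins);
    isolated query genes do not appear in the result.
    """
    if ((edge_table["score"] < 0) | (edge_table["score"] > 1)).any():
        raise ParseError("PPI scores must lie in [0, 1]")
    qset = set(query_genes)
    g = nx.Graph()
    kept = edge_table[edge_table["score"] > score_cutoff]
    for a, b, score in kept[["a", "b", "score"]].itertuples(index=False):
        if a == b or a not in qset or b not in qset:
            continue
        if g.has_edge(a, b):
            if score <= g[a][b]["score"]:
                continue
        g.add_edge(str(a), str(b), score=float(score))
    return g


def _density(n_nodes: int, n_edges: int) -> float:
    if n_nodes < 2:
        return 0.0
    return 2.0 * n_edges / (n_nodes * (n_nodes - 1))


def mcode_vertex_weights(g: nx.Graph) -> dict[str, float]:
    """Bader-Hogue vertex weight: k * density of the top k-core of N[v]."""
    weights: dict[str, float] = {}
    for v in g.nodes:
        nbrs = set(g.neighbors(v)) | {v}
        if len(nbrs) < 2:
            weights[v] = 0.0
            continue
        sub = g.subgraph(nbrs)
        core_nums = nx.core_number(sub)
        k = max(core_nums.values())
        if k == 0:
            weights[v] = 0.0
            continue
        core_nodes = [u for u, c in core_nums.items() if c >= k]
        core = sub.subgraph(core_nodes)
        weights[v] = k * _density(core.number_of_nodes(), core.number_of_edges())
    return weights


def mcode_complexes(
    g: nx.Graph,
    node_score_cutoff: float = DEFAULT_NODE_SCORE_CUTOFF,
    degree_cutoff: int = DEFAULT_DEGREE_CUTOFF,
    haircut: bool = True,
    weights: dict[str, float] | None = None,
) -> list[Complex]:
    """Seeded complex growth, haircut, and density x size scoring.

    Each vertex joins at most one complex.  Ties in seed order and in the
    final ranking are broken deterministically (larger weight first, then
    lexicographic id), so the output is independent of edge insertion order.
    """
    if weights is None:
        weights = mcode_vertex_weights(g)
    order = sorted(g.nodes, key=lambda v: (-weights[v], v))
    assigned: set[str] = set()
    complexes: list[Complex] = []
    for seed in order:
        if seed in assigned:
            continue
        threshold = (1.0 - node_score_cutoff) * weights[seed]
        members = {seed}
        frontier = [seed]
        while frontier:
            nxt = []
            for v in frontier:
                for u in sorted(g.neighbors(v)):
                    if u in assigned or u in members:
                        continue
                    if weights[u] >= threshold:
                        members.add(u)
                        nxt.append(u)
            frontier = nxt
        assigned |= members
        if haircut:
            while True:
                sub = g.subgraph(members)
                weak = [v for v in members if sub.degree(v) < degree_cutoff]
                if not weak:
                    break
                members -= set(weak)
        if len(members) < 2:
            continue
        sub = g.subgraph(members)
        n, e = sub.number_of_nodes(), sub.number_of_edges()
        dens = _density(n, e)
        complexes.append(
            Complex(
                members=tuple(sorted(members)),
                edge_count=e,
                density=dens,
                score=dens * n,
            )
        )
    complexes.sort(key=lambda c: (-c.score, -len(c.members), c.members))
    return complexes


def select_hub_genes(complexes: list[Complex]) -> list[str]:
    """Members of the top-scoring complex, sorted."""
    if not complexes:
        raise HubSelectionError("no complex detected; cannot select hub genes")
    return sorted(complexes[0].members)
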