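"""Tripartite miRNA-TF-mRNA regulatory network and feed-forward-loop motifs.

A feed-forward loop (FFL) is the closed 3-node circuit in which one miRNA
represses both a TF and an mRNA while that TF also regulates the same mRNA:
edges miRNA->mRNA, miRNA->TF and TF->mRNA must all be present.  Motifs are
ranked by the summed degree of their three nodes in the assembled network
("highest-order subnetwork motifs"), optionally restricted to a named miRNA
family.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .errors import ClassConflictError, ParseError

TF_MRNA = "tf_mrna"
MIRNA_MRNA = "mirna_mrna"
MIRNA_TF = "mirna_tf"
EDGE_TYPES = (TF_MRNA, MIRNA_MRNA, MIRNA_TF)

DEFAULT_TF_P_CUTOFF = 0.001


@dataclass
class RegulatoryEdgeSet:
    """Typed directed edges plus the inferred molecular class of each node."""

    edges: pd.DataFrame  # columns: source, target, type
    mirnas: set[str] = field(default_factory=set)
    tfs: set[str] = field(default_factory=set)
    mrnas: set[str] = field(default_factory=set)

    def __post_init__(self):
        for col in ("source", "target", "type"):
            if col not in self.edges.columns:
                raise ParseError(f"edge table lacks column '{col}'")
        bad = set(self.edges["type"]) - set(EDGE_TYPES)
        if bad:
            raise ParseError(f"unknown edge type(s): {sorted(bad)}")
        self.edges = self.edges.drop_duplicates(
            ["source", "target", "type"]
        ).reset_index(drop=True)
        if not (self.mirnas or self.tfs or self.mrnas):
            self._infer_classes()
        self._check_classes()

    def _infer_classes(self) -> None:
        for src, tgt, typ in self.edges[["source", "target", "type"]].itertuples(
            index=False
        ):
            if typ == TF_MRNA:
                self.tfs.add(src)
                self.mrnas.add(tgt)
            elif typ == MIRNA_MRNA:
                self.mirnas.add(src)
                self.mrnas.add(tgt)
            else:  # MIRNA_TF
                self.mirnas.add(src)
                self.tfs.add(tgt)

    def _check_classes(self) -> None:
        for a, b, name in (
            (self.mirnas, self.tfs, "miRNA/TF"),
            (self.mirnas, self.mrnas, "miRNA/mRNA"),
            (self.tfs, self.mrnas, "TF/mRNA"),
        ):
            clash = a & b
            if clash:
                raise ClassConflictError(
                    f"node(s) {sorted(clash)[:5]} appear in both classes {name}"
                )

    def degrees(self) -> dict[str, int]:
        """Incident-edge count per node, direction and type ignored."""
        deg: dict[str, int] = {
            n: 0 for n in self.mirnas | self.tfs | self.mrnas
        }
        for src, tgt in self.edges[["source", "target"]].itertuples(index=False):
            deg[src] += 1
            deg[tgt] += 1
        return deg

    def write(self, path: str | Path) -> None:
        self.edges.sort_values(["type", "source", "target"]).to_csv(
            path, sep="\t", index=False
        )

    @classmethod
    def read(cls, path: str | Path) -> "RegulatoryEdgeSet":
        df = pd.read_csv(path, sep="\t", dtype=str)
        return cls(df[["source", "target", "type"]])


@dataclass(frozen=True)
class FFLMotif:
    mirna_id: str
    tf_id: str
    mrna_id: str
    degree_sum: int = 0

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.mirna_id, self.tf_id, self.mrna_id)


@dataclass(frozen=True)
class NetworkStats:
    n_mirnas: int
    n_tfs: int
    n_mrnas: int
    n_edges_tf_mrna: int
    n_edges_mirna_mrna: int
    n_edges_mirna_tf: int
    degree_range: dict[str, tuple[int, int]]
    avg_degree: dict[str, float]

    @property
    def total_nodes(self) -> int:
        return self.n_mirnas + self.n_tfs + self.n_mrnas

    @property
    def total_edges(self) -> int:
        return (
            self.n_edges_tf_mrna + self.n_edges_mirna_mrna + self.n_edges_mirna_tf
        )


def build_regulatory_network(
    hub_mrnas: list[str],
    tf_table: pd.DataFrame,
    mirna_edges: pd.DataFrame,
    dems: list[str],
    tf_p_cutoff: float = DEFAULT_TF_P_CUTOFF,
) -> RegulatoryEdgeSet:
    """Assemble the tripartite network from regulatory evidence tables.

    TF->mRNA rows (columns tf, target, p) are kept when the target is a hub
    mRNA and p <= cutoff (inclusive).  miRNA edge rows (source, target,
    type in {mirna_mrna, mirna_tf}) are kept when the miRNA is a DEM and
    the target is a hub mRNA (mirna_mrna) or a retained TF (mirna_tf).
    """
    if ((tf_table["p"] <= 0) | (tf_table["p"] > 1)).any():
        raise ParseError("TF table p-values must lie in (0, 1]")
    hubs = set(hub_mrnas)
    demset = set(dems)
    tf_rows = tf_table[(tf_table["p"] <= tf_p_cutoff) & tf_table["target"].isin(hubs)]
    retained_tfs = set(tf_rows["tf"])
    rows = [
        {"source": tf, "target": tgt, "type": TF_MRNA}
        for tf, tgt in tf_rows[["tf", "target"]].itertuples(index=False)
    ]
    for src, tgt, typ in mirna_edges[["source", "target", "type"]].itertuples(
        index=False
    ):
        if src not in demset:
            continue
        if typ == MIRNA_MRNA and tgt in hubs:
            rows.append({"source": src, "target": tgt, "type": MIRNA_MRNA})
        elif typ == MIRNA_TF and tgt in retained_tfs:
            rows.append({"source": src, "target": tgt, "type": MIRNA_TF})
    edges = pd.DataFrame(rows, columns=["source", "target", "type"])
    return RegulatoryEdgeSet(edges)


def enumerate_ffls(net: RegulatoryEdgeSet) -> list[FFLMotif]:
    """All closed (miRNA, TF, mRNA) triples, sorted by ids."""
    m2g: dict[str, set[str]] = {}
    m2t: dict[str, set[str]] = {}
    t2g: dict[str, set[str]] = {}
    for src, tgt, typ in net.edges[["source", "target", "type"]].itertuples(
        index=False
    ):
        if typ == MIRNA_MRNA:
            m2g.setdefault(src, set()).add(tgt)
        elif typ == MIRNA_TF:
            m2t.setdefault(src, set()).add(tgt)
        else:
            t2g.setdefault(src, set()).add(tgt)
    motifs = []
    for m in m2g.keys() & m2t.keys():
        for t in m2t[m]:
            for g in t2g.get(t, set()) & m2g[m]:
                motifs.append(FFLMotif(m, t, g))
    motifs.sort(key=lambda x: x.key)
    return motifs


def network_stats(net: RegulatoryEdgeSet) -> NetworkStats:
    """Node/edge counts per class and type plus degree summaries."""
    deg = net.degrees()
    by_type = net.edges["type"].value_counts().to_dict()

    def _summary(nodes: set[str]) -> tuple[tuple[int, int], float]:
        if not nodes:
            return (0, 0), 0.0
        ds = [deg[n] for n in nodes]
        return (min(ds), max(ds)), sum(ds) / len(nodes)

    rng_m, avg_m = _summary(net.mirnas)
    rng_t, avg_t = _summary(net.tfs)
    rng_g, avg_g = _summary(net.mrnas)
    return NetworkStats(
        n_mirnas=len(net.mirnas),
        n_tfs=len(net.tfs),
        n_mrnas=len(net.mrnas),
        n_edges_tf_mrna=by_type.get(TF_MRNA, 0),
        n_edges_mirna_mrna=by_type.get(MIRNA_MRNA, 0),
        n_edges_mirna_tf=by_type.get(MIRNA_TF, 0),
        degree_range={"mirna": rng_m, "tf": rng_t, "mrna": rng_g},
        avg_degree={"mirna": avg_m, "tf": avg_t, "mrna": avg_g},
    )


def rank_motifs(
    motifs: list[FFLMotif],
    net: RegulatoryEdgeSet,
    family: list[str] | None = None,
) -> list[FFLMotif]:
    """Rank motifs by summed node degree (descending), ties by ids.

    ``family`` optionally restricts to motifs whose miRNA is in the list
    before ranking.
    """
    deg = net.degrees()
    if family is not None:
        fam = set(family)
        motifs = [m for m in motifs if m.mirna_id in fam]
    scored = [
        FFLMotif(
            m.mirna_id,
            m.tf_id,
            m.mrna_id,
            degree_sum=deg.get(m.mirna_id, 0)
            + deg.get(m.tf_id, 0)
            + deg.get(m.mrna_id, 0),
        )
        for m in motifs
    ]
    scored.sort(key=lambda m: (-m.degree_sum, m.key))
    return scored
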