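"""Immune-gene intersection and hypergeometric over-representation analysis.

Differential genes are intersected with an immune-related-gene list to give
DEIRGs (differentially expressed immune-related genes); DEIRGs are then
tested for over-representation in GMT gene-set collections with the exact
hypergeometric upper tail P(X >= k), BH-adjusted within each namespace.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from scipy import stats

from .dea import bh_adjust
from .errors import UniverseError, ParseError


@dataclass
class GeneSetCollection:
    """Named gene sets sharing one namespace tag (BP/MF/CC/pathway)."""

    sets: dict[str, list[str]]
    namespace: str = "pathway"

    def __post_init__(self):
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set '{name}' is empty")
            uniq = list(dict.fromkeys(members))
            self.sets[name] = uniq

    @classmethod
    def from_gmt(cls, path: str | Path, namespace: str = "pathway") -> "GeneSetCollection":
        """Read a GMT file: name <tab> description <tab> member ids."""
        sets: dict[str, list[str]] = {}
        with open(path) as fh:
            for i, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line:
                    continue
                parts = line.split("\t")
                if len(parts) < 3:
                    raise ParseError("GMT line needs name, description, members", i)
                sets[parts[0]] = [g for g in parts[2:] if g]
        return cls(sets, namespace)

    def to_gmt(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for name in self.sets:
                fh.write("\t".join([name, self.namespace] + self.sets[name]) + "\n")


@dataclass(frozen=True)
class EnrichmentRow:
    set_name: str
    overlap_k: int
    set_size_K: int
    query_n: int
    universe_N: int
    p: float
    q: float = field(default=float("nan"))
    significant: bool = False


def intersect_immune(degs: list[str], irg_list: list[str]) -> list[str]:
    """DEGs that are also immune-related; input order of ``degs`` preserved."""
    irg = set(irg_list)
    seen: set[str] = set()
    out = []
    for g in degs:
        if g in irg and g not in seen:
            out.append(g)
            seen.add(g)
    return out


def ora_test(query: list[str], gene_set: list[str], universe: list[str]) -> EnrichmentRow:
    """Exact hypergeometric upper-tail over-representation test.

    p = P(X >= k) where k = |query ∩ set|, K = |set ∩ universe|,
    n = |query|, N = |universe|.
    """
    uni = set(universe)
    q = list(dict.fromkeys(query))
    if not set(q) <= uni:
        missing = sorted(set(q) - uni)[:5]
        raise UniverseError(f"query genes outside universe, e.g. {missing}")
    s = set(gene_set) & uni
    k = len(set(q) & s)
    K, n, N = len(s), len(q), len(uni)
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    return EnrichmentRow(
        set_name="", overlap_k=k, set_size_K=K, query_n=n, universe_N=N,
        p=min(p, 1.0),
    )


def enrich_collection(
    query: list[str],
    collection: GeneSetCollection,
    universe: list[str],
    q_cutoff: float = 1e-4,
) -> pd.DataFrame:
    """ORA over every set in one collection, BH-adjusted within the namespace.

    Returns a DataFrame sorted by p with columns set_name, namespace,
    overlap_k, set_size_K, query_n, universe_N, p, q, significant, and a
    ``covered_genes`` attribute listing query genes in >= 1 significant set.
    """
    if not collection.sets:
        raise ValueError("empty gene-set collection")
    rows = []
    qset = set(query)
    for name, members in collection.sets.items():
        r = ora_test(query, members, universe)
        rows.append(
            {
                "set_name": name,
                "namespace": collection.namespace,
                "overlap_k": r.overlap_k,
                "set_size_K": r.set_size_K,
                "query_n": r.query_n,
                "universe_N": r.universe_N,
                "p": r.p,
                "overlap_genes": sorted(qset & set(members)),
            }
        )
    df = pd.DataFrame(rows)
    df["q"] = bh_adjust(df["p"].to_numpy())
    df["significant"] = df["q"] < q_cutoff
    df = df.sort_values(["p", "set_name"], kind="mergesort").reset_index(drop=True)
    covered: set[str] = set()
    for _, row in df[df["significant"]].iterrows():
        covered |= set(row["overlap_genes"])
    df.attrs["covered_genes"] = sorted(covered)
    return df


def read_gene_list(path: str | Path) -> list[str]:
    """One symbol per line; blank lines ignored, order preserved."""
    with open(path) as fh:
        return [ln.strip() for ln in fh if ln.strip()]


def write_gene_list(genes: list[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\n".join(genes) + ("\n" if genes else ""))
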