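"""Over-representation analysis of gene lists against gene-set collections.

One-sided hypergeometric test per set (the classic ORA behind GO/KEGG
tools), with Benjamini-Hochberg adjustment across the tested sets. The
universe is the population the query was drawn from — here, all genes of
the relevant expression matrix — and genes outside it are dropped from
both query and sets before testing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd
from scipy.stats import hypergeom

from .diffexpr import bh_adjust

logger = logging.getLogger(__name__)

__all__ = [
    "GeneSetCollection",
    "hypergeometric_test",
    "enrich",
    "read_gmt",
    "write_gmt",
]


@dataclass
class GeneSetCollection:
    """Named gene sets plus the background universe.

    sets: name -> (description, member genes). Sets restricted to the
    universe must stay non-empty to be testable.
    """

    sets: dict[str, tuple[str, frozenset[str]]]
    universe: frozenset[str]

    def __post_init__(self) -> None:
        for name, (_, members) in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")

    def restricted(self) -> dict[str, tuple[str, frozenset[str]]]:
        """Sets intersected with the universe; empty results are dropped."""
        out = {}
        for name, (desc, members) in self.sets.items():
            inter = members & self.universe
            if inter:
                out[name] = (desc, inter)
        return out


def hypergeometric_test(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail hypergeometric p-value P(X >= k).

    Drawing n genes from a universe of N containing K set members,
    p = sum_{i=k}^{min(K,n)} C(K,i) C(N-K,n-i) / C(N,n). Evaluated via
    scipy's log-space-stable survival function.
    """
    if not (0 <= k <= min(K, n)):
        raise ValueError(f"need 0 <= k <= min(K, n); got k={k}, K={K}, n={n}")
    if K > N or n > N:
        raise ValueError("set and query sizes cannot exceed the universe")
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


def enrich(query, collection: GeneSetCollection, alpha: float = 0.05) -> pd.DataFrame:
    """Test every gene set against the query; one row per set with overlap >= 1.

    Genes outside the universe are dropped. Significance is flagged at raw
    p < alpha (the convention of most published ORA figure filters); a
    BH-FDR column is always reported alongside. Sorted by p, then name.
    """
    if not collection.universe:
        raise ValueError("empty universe")
    q = frozenset(query) & collection.universe
    if not q:
        raise ValueError("query has no genes in the universe")
    N, n = len(collection.universe), len(q)
    rows = []
    for name, (desc, members) in collection.restricted().items():
        k = len(q & members)
        if k < 1:
            continue
        K = len(members)
        rows.append(
            {
                "term": name,
                "description": desc,
                "k": k,
                "K": K,
                "n": n,
                "N": N,
                "pvalue": hypergeometric_test(k, K, n, N),
            }
        )
    if not rows:
        return pd.DataFrame(
            columns=["term", "description", "k", "K", "n", "N", "pvalue", "fdr", "significant"]
        )
    df = pd.DataFrame(rows)
    df["fdr"] = bh_adjust(df["pvalue"].to_numpy())
    df["significant"] = df["pvalue"] < alpha
    df = df.sort_values(["pvalue", "term"], kind="mergesort").reset_index(drop=True)
    logger.info("enrichment: %d sets tested, %d significant at p < %g", len(df), int(df["significant"].sum()), alpha)
    return df


def read_gmt(path, universe=None) -> GeneSetCollection:
    """Read a GMT file (name, description, tab-separated members per line).

    If ``universe`` is None it defaults to the union of all set members.
    """
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: line {lineno}: GMT needs name, description, >= 1 member")
            name, desc, members = fields[0], fields[1], [m for m in fields[2:] if m]
            if name in sets:
                raise ValueError(f"{path}: line {lineno}: duplicate set name {name!r}")
            sets[name] = (desc, frozenset(members))
    if universe is None:
        universe = frozenset().union(*(m for _, m in sets.values())) if sets else frozenset()
    return GeneSetCollection(sets=sets, universe=frozenset(universe))


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, (desc, members) in collection.sets.items():
            fh.write("\t".join([name, desc, *sorted(members)]) + "\n")
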