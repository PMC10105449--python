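"""Hypergeometric gene-set over-representation analysis (ORA).

Tests a query gene list against a GMT collection: for each set the
upper-tail hypergeometric probability P(X >= k) of drawing k or more set
members in a query of size n from a universe of size N containing K set
members, with Benjamini-Hochberg correction across sets.  The universe
defaults to all genes in the expression data, not all genes in the
collection — ORA is sensitive to this choice, so it is explicit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd
from scipy import stats

from .diffexpr import bh_adjust

log = logging.getLogger(__name__)

__all__ = ["GeneSetCollection", "read_gmt", "write_gmt", "ora_test"]


@dataclass
class GeneSetCollection:
    sets: dict          # name -> set of gene ids
    universe: set
    descriptions: dict | None = None

    def restricted(self, universe: set) -> "GeneSetCollection":
        """Intersect every set with ``universe``; drop emptied sets."""
        sets = {}
        for name, members in self.sets.items():
            kept = members & universe
            if kept:
                sets[name] = kept
            else:
                log.warning("set %r empty after universe restriction", name)
        return GeneSetCollection(sets, set(universe), self.descriptions)


def read_gmt(path) -> GeneSetCollection:
    """Parse a GMT file (name, description, tab-separated members).

    Duplicate members are deduplicated; empty lines skipped; malformed
    lines reported with their line number.
    """
    sets, descriptions = {}, {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line needs name, description "
                    f"and at least one member")
            name, desc = fields[0], fields[1]
            members = {g for g in fields[2:] if g}
            if not members:
                raise ValueError(f"{path}:{lineno}: set {name!r} has no members")
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate set name {name!r}")
            sets[name] = members
            descriptions[name] = desc
    universe = set().union(*sets.values()) if sets else set()
    return GeneSetCollection(sets, universe, descriptions)


def write_gmt(collection: GeneSetCollection, path) -> None:
    desc = collection.descriptions or {}
    with open(path, "w") as fh:
        for name in sorted(collection.sets):
            members = sorted(collection.sets[name])
            fh.write("\t".join([name, desc.get(name, "na"), *members]) + "\n")


def ora_test(query, collection: GeneSetCollection,
             universe=None) -> pd.DataFrame:
    """Over-representation of ``query`` in every set of ``collection``.

    Returns a DataFrame ordered by decreasing gene ratio then increasing
    p, with columns k, K, n, N, gene_ratio, pvalue, padj, genes.  Query
    genes outside the universe are dropped with a warning.
    """
    universe = set(universe) if universe is not None else set(collection.universe)
    query = set(query)
    outside = query - universe
    if outside:
        log.warning("dropping %d query genes outside the universe", len(outside))
        query &= universe
    if not query:
        raise ValueError("query is empty after universe intersection")
    coll = collection.restricted(universe)
    big_n = len(universe)
    n = len(query)
    rows = []
    for name in sorted(coll.sets):
        members = coll.sets[name]
        big_k = len(members)
        overlap = sorted(query & members)
        k = len(overlap)
        p = float(stats.hypergeom.sf(k - 1, big_n, big_k, n))
        rows.append({"set": name, "k": k, "K": big_k, "n": n, "N": big_n,
                     "pvalue": min(p, 1.0), "genes": ",".join(overlap)})
    res = pd.DataFrame(rows).set_index("set")
    in_any = len(query & set().union(*coll.sets.values())) if coll.sets else 0
    res["gene_ratio"] = res["k"] / in_any if in_any else 0.0
    res["padj"] = bh_adjust(res["pvalue"].to_numpy())
    return res.sort_values(["gene_ratio", "pvalue"],
                           ascending=[False, True])
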