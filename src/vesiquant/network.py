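"""Interaction-network annotation of quantitation results.

Joins the quantitation summary to a protein-protein interaction edge list
(two-column TSV or SIF), emitting a node-attribute table with the
Diff-NSAF color scheme for import into standard network tools, and
partitions the interaction neighborhoods of two kinase seed sets (e.g. PKA
vs PKC subunits) into exclusive and shared interactors.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

from .quantitation import CLASS_GREY, QuantResult

logger = logging.getLogger(__name__)


def read_edges(path: str | Path) -> nx.Graph:
    """Read an undirected edge list from TSV (2/3 columns) or SIF.

    Symbols are upper-cased; self-loops are dropped.  SIF rows are
    ``node<tab>relation<tab>node [node ...]``.
    """
    path = Path(path)
    graph = nx.Graph()
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if path.suffix.lower() == ".sif":
                if len(parts) < 3:
                    continue  # isolated node line
                src, targets = parts[0], parts[2:]
            else:
                if len(parts) < 2:
                    raise ValueError(
                        f"{path}:{line_no}: expected at least two columns")
                src, targets = parts[0], [parts[1]]
            for dst in targets:
                a, b = src.upper(), dst.upper()
                if a != b:
                    graph.add_edge(a, b)
    return graph


def node_attributes(
    quant: QuantResult | pd.DataFrame,
    symbols: Mapping[str, str],
    categories: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """One node-attribute row per protein in the quantitation summary.

    Accepts a :class:`~vesiquant.quantitation.QuantResult` or its summary
    frame.  Quantitated proteins carry their Diff-NSAF class; identified-
    but-unquantitated proteins are emitted grey.  Proteins without a
    resolvable symbol keep their accession, with a warning; duplicate
    symbols are suffixed to stay unique.
    """
    summary = getattr(quant, "summary", quant)
    categories = categories or {}
    rows = []
    seen: dict[str, int] = {}
    unresolved = 0
    for pid, row in summary.iterrows():
        symbol = symbols.get(pid, "")
        if not symbol:
            unresolved += 1
            symbol = pid
        symbol = symbol.upper()
        if symbol in seen:
            seen[symbol] += 1
            suffixed = f"{symbol}_{seen[symbol]}"
            logger.warning("duplicate symbol %s -> %s", symbol, suffixed)
            symbol = suffixed
        else:
            seen[symbol] = 1
        quantitated = bool(row["quantitated_soluble"]
                           or row["quantitated_membrane"])
        rows.append({
            "symbol": symbol,
            "diff_nsaf": row["diff_nsaf_scaled"] if quantitated else "",
            "class": row["dist_class"] if quantitated else CLASS_GREY,
            "category": categories.get(pid, ""),
            "quantitated": quantitated,
        })
    if unresolved:
        logger.warning("%d proteins without symbol mapping kept by accession",
                       unresolved)
    return pd.DataFrame(rows,
                        columns=["symbol", "diff_nsaf", "class",
                                 "category", "quantitated"])


def kinase_partition(
    edges: nx.Graph,
    set_a_seeds: Iterable[str],
    set_b_seeds: Iterable[str],
) -> tuple[set[str], set[str], set[str]]:
    """Partition seed neighborhoods into A-only, B-only, and shared.

    Neighbors of any seed in A versus any seed in B; seeds themselves are
    excluded from all three sets.  Absent seeds contribute empty
    neighborhoods.
    """
    seeds_a = {s.upper() for s in set_a_seeds}
    seeds_b = {s.upper() for s in set_b_seeds}

    def neighborhood(seeds: set[str]) -> set[str]:
        out: set[str] = set()
        for s in seeds:
            if s in edges:
                out.update(edges.neighbors(s))
        return out - seeds_a - seeds_b

    na, nb = neighborhood(seeds_a), neighborhood(seeds_b)
    return na - nb, nb - na, na & nb
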