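"""Protein similarity clustering and minimal-redundant protein inference.

The protein database is collapsed by single-linkage clustering of pairwise
global-alignment similarity (edges at >=95% identity over >=90% of the
shorter sequence), and identified peptides are then explained by the
smallest set of proteins that covers them all.  Isoforms and close
homologues enter the reported set only when a peptide unique to them
requires it, which is the behaviour that keeps spectral counts from being
split across redundant database entries downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, NamedTuple, Sequence

import networkx as nx
import pandas as pd
from Bio import Align

from .records import ProteinRecord

logger = logging.getLogger(__name__)


class PeptideEvidence(NamedTuple):
    peptide: str
    protein_ids: frozenset[str]


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = 0.0
    # Identity counting wants match +1 / mismatch 0 / gap 0.  An exactly
    # zero gap score makes the optimal alignment (and hence the column
    # count) degenerate, so gaps carry an infinitesimal penalty: the match
    # count is unchanged and the traceback picks the fewest-gap optimum.
    aligner.open_gap_score = -1e-6
    aligner.extend_gap_score = -1e-6
    return aligner


_ALIGNER = _make_aligner()


def pairwise_identity(seq_a: str, seq_b: str) -> tuple[float, float]:
    """Global-alignment identity and coverage between two sequences.

    identity = identical aligned positions / alignment columns excluding
    terminal gaps; coverage = the aligned span on the shorter sequence /
    length of the shorter sequence.
    """
    if not seq_a or not seq_b:
        raise ValueError("sequences must be non-empty")
    aln = _ALIGNER.align(seq_a, seq_b)[0]
    a_blocks, b_blocks = aln.aligned
    if len(a_blocks) == 0:
        return 0.0, 0.0
    matches = 0
    aligned_cols = 0
    internal_gaps = 0
    for i, ((a0, a1), (b0, b1)) in enumerate(zip(a_blocks, b_blocks)):
        aligned_cols += a1 - a0
        matches += sum(x == y for x, y in zip(seq_a[a0:a1], seq_b[b0:b1]))
        if i:
            internal_gaps += (a0 - a_blocks[i - 1][1]) + (b0 - b_blocks[i - 1][1])
    cols = aligned_cols + internal_gaps
    identity = matches / cols if cols else 0.0
    if len(seq_a) <= len(seq_b):
        span = a_blocks[-1][1] - a_blocks[0][0]
        coverage = span / len(seq_a)
    else:
        span = b_blocks[-1][1] - b_blocks[0][0]
        coverage = span / len(seq_b)
    return identity, coverage


@dataclass
class ClusterAssignment:
    """Partition of the protein database into similarity clusters."""

    cluster_of: dict[str, str]          # protein id -> cluster id
    representative_of: dict[str, str]   # cluster id -> representative protein
    seq_length: dict[str, int] = field(default_factory=dict)

    def representative(self, protein_id: str) -> str:
        return self.representative_of[self.cluster_of[protein_id]]

    def is_representative(self, protein_id: str) -> bool:
        return self.representative(protein_id) == protein_id

    def to_frame(self) -> pd.DataFrame:
        rows = [{"protein": p, "cluster": c,
                 "representative": self.representative_of[c]}
                for p, c in sorted(self.cluster_of.items())]
        return pd.DataFrame(rows, columns=["protein", "cluster", "representative"])


def cluster_proteins(
    proteins: Sequence[ProteinRecord],
    identity_min: float = 0.95,
    coverage_min: float = 0.90,
) -> ClusterAssignment:
    """Single-linkage clustering of proteins by alignment similarity.

    An edge joins two proteins when identity >= ``identity_min`` and
    coverage >= ``coverage_min``; clusters are the connected components.
    The representative is the longest member (ties broken by lexicographic
    id), and cluster ids are derived from the smallest member id so the
    partition is invariant under input order.
    """
    recs = sorted(proteins, key=lambda r: r.id)
    by_id = {r.id: r for r in recs}
    graph = nx.Graph()
    graph.add_nodes_from(r.id for r in recs)

    # seed prescreen: <=5% non-identical columns forces a common clean run
    # of >= (0.95 n)/(0.05 n + 1) ~ 19 residues, so any qualifying pair of
    # sequences longer than ~40 shares an identical 8-mer; an inverted
    # k-mer index finds those pairs without touching the O(n^2) majority
    kmer = 8
    index: dict[str, list[str]] = {}
    for r in recs:
        for i in range(len(r.sequence) - kmer + 1):
            index.setdefault(r.sequence[i:i + kmer], []).append(r.id)
    candidates: set[tuple[str, str]] = set()
    for ids in index.values():
        if len(ids) > 1:
            for pair in combinations(sorted(set(ids)), 2):
                candidates.add(pair)
    short = [r.id for r in recs if len(r.sequence) < 40]
    for sid in short:
        for r in recs:
            if r.id != sid:
                candidates.add(tuple(sorted((sid, r.id))))

    for ida, idb in sorted(candidates):
        ra, rb = by_id[ida], by_id[idb]
        shorter = min(len(ra.sequence), len(rb.sequence))
        # a qualifying pair needs >= identity_min * coverage_min * shorter
        # matches, and the alignment score equals the match count
        score = _ALIGNER.score(ra.sequence, rb.sequence)
        if score < identity_min * coverage_min * shorter - 0.5:
            continue
        identity, coverage = pairwise_identity(ra.sequence, rb.sequence)
        if identity >= identity_min and coverage >= coverage_min:
            graph.add_edge(ra.id, rb.id)

    cluster_of: dict[str, str] = {}
    representative_of: dict[str, str] = {}
    for comp in nx.connected_components(graph):
        members = sorted(comp)
        cid = f"CL_{members[0]}"
        rep = min(members, key=lambda p: (-len(by_id[p].sequence), p))
        representative_of[cid] = rep
        for p in members:
            cluster_of[p] = cid
    return ClusterAssignment(
        cluster_of, representative_of,
        {r.id: len(r.sequence) for r in recs})


def evidence_from_psms(psms: pd.DataFrame) -> list[PeptideEvidence]:
    """Distinct peptides with the union of their matched target proteins."""
    if psms.empty:
        return []
    tgt = psms[~psms["is_decoy"].astype(bool)] if "is_decoy" in psms else psms
    grouped = tgt.groupby("peptide")["proteins"].agg(
        lambda s: frozenset(p for entry in s for p in entry.split(";")))
    return [PeptideEvidence(pep, ids) for pep, ids in sorted(grouped.items())]


_EXACT_LIMIT = 22


def minimal_protein_set(
    evidence: Iterable[PeptideEvidence],
    clusters: ClusterAssignment,
) -> set[str]:
    """Smallest protein set explaining every peptide.

    Set cover with a preference order that admits cluster representatives
    before other members, then longer sequences, then lexicographically
    smaller ids.  Proteins that are the sole match of some peptide are
    forced in; dominated candidates (peptide sets contained in a preferred
    candidate's) are eliminated; the residual instance is solved exactly by
    branch and bound when small enough, otherwise greedily with an
    irredundancy pruning pass.  The result always covers all peptides and
    no member can be removed without uncovering one.
    """
    evidence = list(evidence)
    for ev in evidence:
        if not ev.protein_ids:
            raise ValueError(f"peptide {ev.peptide!r} has no matching proteins")
        unknown = ev.protein_ids - clusters.cluster_of.keys()
        if unknown:
            raise ValueError(
                f"peptide {ev.peptide!r} matches unclustered proteins: "
                f"{sorted(unknown)}")
    if not evidence:
        return set()

    def pref(pid: str):
        return (not clusters.is_representative(pid),
                -clusters.seq_length.get(pid, 0), pid)

    # distinct protein-sets are the effective universe
    sigs = sorted({ev.protein_ids for ev in evidence},
                  key=lambda s: sorted(s))
    forced = {next(iter(s)) for s in sigs if len(s) == 1}
    remaining = [s for s in sigs if not (s & forced)]

    covers: dict[str, set[int]] = {}
    for i, s in enumerate(remaining):
        for pid in s:
            covers.setdefault(pid, set()).add(i)
    candidates = sorted(covers, key=pref)

    # dominance elimination preserves the minimum cover cardinality
    changed = True
    while changed:
        changed = False
        for a in list(candidates):
            for b in candidates:
                if b == a:
                    continue
                if covers[a] < covers[b] or (covers[a] == covers[b]
                                             and pref(b) < pref(a)):
                    candidates.remove(a)
                    del covers[a]
                    changed = True
                    break
            if changed:
                break

    universe = set(range(len(remaining)))
    if not universe:
        return set(forced)

    chosen = (_exact_cover(universe, covers, candidates)
              if len(candidates) <= _EXACT_LIMIT
              else _greedy_cover(universe, covers, candidates))
    result = forced | chosen

    # irredundancy: drop any member whose peptides stay covered without it
    # (forced members are sole owners of a peptide, hence never removable)
    def covered_by(pids: set[str]) -> bool:
        return all(ev.protein_ids & pids for ev in evidence)

    for pid in sorted(result - forced, key=pref, reverse=True):
        trial = result - {pid}
        if trial and covered_by(trial):
            result = trial
    return result


def _greedy_cover(universe: set[int], covers: Mapping[str, set[int]],
                  order: list[str]) -> set[str]:
    uncovered = set(universe)
    chosen: set[str] = set()
    while uncovered:
        gains = {p: len(covers[p] & uncovered) for p in order}
        gain = max(gains.values(), default=0)
        if gain == 0:
            raise ValueError("uncoverable peptides remain")
        # ties broken by the preference order (already sorted)
        best = next(p for p in order if gains[p] == gain)
        chosen.add(best)
        uncovered -= covers[best]
    return chosen


def _exact_cover(universe: set[int], covers: Mapping[str, set[int]],
                 order: list[str]) -> set[str]:
    """Minimum set cover by depth-first branch and bound."""
    best = _greedy_cover(universe, covers, order)
    max_size = max((len(s) for s in covers.values()), default=1)

    def dfs(uncovered: frozenset[int], chosen: tuple[str, ...]):
        nonlocal best
        if not uncovered:
            if len(chosen) < len(best):
                best = set(chosen)
            return
        lower = len(chosen) + -(-len(uncovered) // max_size)
        if lower >= len(best):
            return
        # branch on the uncovered element with fewest covering candidates
        target = min(uncovered,
                     key=lambda e: sum(1 for p in order if e in covers[p]))
        for p in order:
            if target in covers[p] and p not in chosen:
                dfs(uncovered - covers[p], chosen + (p,))

    dfs(frozenset(universe), ())
    return best
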