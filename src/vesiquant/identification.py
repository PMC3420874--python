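"""PSM filtering by per-charge score/%SPI thresholds and decoy-based FDR.

Peptide-spectrum matches are accepted when they meet their charge state's
minimum score and a %SPI floor (score >=13, %SPI >=70 for +1/+2 precursors;
score >=16 for +3).  PSMs that miss the primary cut but reach a relaxed
score (>=10, %SPI >=70) are *rescued* when the protein they map to is
supported by two or more distinct peptides across the accepted-plus-
candidate pool.  Decoy PSMs are filtered by the same rules but reported
separately: they feed the false-discovery-rate estimate
``FDR = decoy identifications / real identifications`` and never enter
protein inference or quantitation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, NamedTuple

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

KNOWN_CHARGES = (1, 2, 3)


@dataclass(frozen=True)
class ThresholdSet:
    """Per-charge acceptance thresholds plus the two-peptide rescue rule."""

    min_score: Mapping[int, float] = field(
        default_factory=lambda: {1: 13.0, 2: 13.0, 3: 16.0})
    min_spi: float = 70.0
    rescue_score: float = 10.0
    rescue_spi: float = 70.0
    rescue_min_peptides: int = 2

    def validate(self) -> None:
        if any(self.rescue_score > s for s in self.min_score.values()):
            raise ValueError("rescue_score must not exceed any per-charge cut")


class FilterResult(NamedTuple):
    """Target and decoy PSMs partitioned by the acceptance rules."""

    accepted: pd.DataFrame
    rescued: pd.DataFrame
    decoy_accepted: pd.DataFrame
    decoy_rescued: pd.DataFrame

    @property
    def target(self) -> pd.DataFrame:
        """All retained target PSMs (primary acceptance plus rescue)."""
        return pd.concat([self.accepted, self.rescued])

    @property
    def decoy(self) -> pd.DataFrame:
        return pd.concat([self.decoy_accepted, self.decoy_rescued])


def _split_proteins(col: pd.Series) -> pd.Series:
    return col.str.split(";")


def apply_thresholds(
    psms: pd.DataFrame, thresholds: ThresholdSet | None = None
) -> FilterResult:
    """Partition PSMs into accepted / rescued, targets and decoys separately.

    Rescue eligibility is peptide-level: within each of the target and decoy
    pools, a sub-threshold candidate (score >= rescue_score, %SPI >=
    rescue_spi) is rescued when at least one of its proteins carries >=
    ``rescue_min_peptides`` distinct peptide sequences over the union of
    accepted PSMs and rescue candidates.  Rows with unknown charge states
    are dropped with a warning.
    """
    th = thresholds or ThresholdSet()
    th.validate()
    if psms.empty:
        empty = psms.iloc[0:0]
        return FilterResult(empty, empty, empty, empty)

    known = psms["charge"].isin(list(th.min_score))
    if not known.all():
        logger.warning("dropping %d PSMs with unknown charge states",
                       (~known).sum())
        psms = psms[known]
    charge_min = psms["charge"].map(dict(th.min_score))
    primary = (psms["score"] >= charge_min) & (psms["spi"] >= th.min_spi)
    candidate = (~primary
                 & (psms["score"] >= th.rescue_score)
                 & (psms["spi"] >= th.rescue_spi))
    is_decoy = psms["is_decoy"].astype(bool) if "is_decoy" in psms \
        else pd.Series(False, index=psms.index)

    rescued = pd.Series(False, index=psms.index)
    for decoy_flag in (False, True):
        grp = is_decoy == decoy_flag
        pool = psms[grp & (primary | candidate)]
        if pool.empty:
            continue
        ev = pool[["peptide"]].assign(protein=_split_proteins(pool["proteins"]))
        ev = ev.explode("protein")
        n_pep = ev.groupby("protein")["peptide"].nunique()
        supported = set(n_pep.index[n_pep >= th.rescue_min_peptides])
        cand = psms[grp & candidate]
        if cand.empty or not supported:
            continue
        ex = cand[[]].assign(protein=_split_proteins(cand["proteins"])).explode("protein")
        hit = ex["protein"].isin(supported).groupby(level=0).any()
        rescued.loc[hit.index[hit]] = True

    return FilterResult(
        accepted=psms[primary & ~is_decoy],
        rescued=psms[candidate & rescued & ~is_decoy],
        decoy_accepted=psms[primary & is_decoy],
        decoy_rescued=psms[candidate & rescued & is_decoy],
    )


@dataclass
class ChargeFDR:
    n_target_pass: int
    n_decoy_pass: int
    fdr: float  # NaN when no targets pass


@dataclass
class FDRReport:
    """Decoy-estimated FDR at a threshold set, with score-binned histograms.

    ``histogram`` has one row per (charge, score bin), bins left-closed with
    the configured width starting at 0, and target/decoy counts whose
    marginals equal the input table sizes.
    """

    per_charge: dict[int, ChargeFDR]
    total: ChargeFDR
    histogram: pd.DataFrame
    thresholds: ThresholdSet

    def to_frame(self) -> pd.DataFrame:
        rows = [{"charge": str(c), "n_target_pass": r.n_target_pass,
                 "n_decoy_pass": r.n_decoy_pass, "fdr": r.fdr}
                for c, r in sorted(self.per_charge.items())]
        rows.append({"charge": "total", "n_target_pass": self.total.n_target_pass,
                     "n_decoy_pass": self.total.n_decoy_pass,
                     "fdr": self.total.fdr})
        return pd.DataFrame(rows)


def _fdr(n_target: int, n_decoy: int) -> float:
    if n_target == 0:
        logger.warning("no passing targets; FDR undefined")
        return math.nan
    return n_decoy / n_target


def compute_fdr(
    target_psms: pd.DataFrame,
    decoy_psms: pd.DataFrame,
    thresholds: ThresholdSet | None = None,
    bin_width: float = 1.0,
) -> FDRReport:
    """Score-binned target/decoy histograms and FDR at the threshold set.

    The FDR is a peptide-level estimate at the primary per-charge
    thresholds (the two-peptide rescue is a protein-level identification
    criterion and is not part of the decoy threshold analysis).  Reported
    for +2 and +3 precursors separately and for all charges combined.
    """
    th = thresholds or ThresholdSet()
    tgt = target_psms.assign(is_decoy=False)
    dec = decoy_psms.assign(is_decoy=True)

    # left-closed bins anchored at 0: bin_left = floor(score / width) * width
    hist_rows = []
    for charge in sorted(set(tgt.get("charge", pd.Series(dtype=int)))
                         | set(dec.get("charge", pd.Series(dtype=int)))):
        t_bin = np.floor(tgt.loc[tgt["charge"] == charge, "score"]
                         / bin_width) * bin_width
        d_bin = np.floor(dec.loc[dec["charge"] == charge, "score"]
                         / bin_width) * bin_width
        t_cnt = t_bin.value_counts()
        d_cnt = d_bin.value_counts()
        for left in sorted(set(t_cnt.index) | set(d_cnt.index)):
            hist_rows.append({"charge": charge, "bin_left": float(left),
                              "target_count": int(t_cnt.get(left, 0)),
                              "decoy_count": int(d_cnt.get(left, 0))})
    histogram = pd.DataFrame(
        hist_rows, columns=["charge", "bin_left", "target_count", "decoy_count"])

    pass_t = apply_thresholds(tgt, th).accepted
    pass_d = apply_thresholds(dec, th).decoy_accepted

    per_charge = {}
    for charge in (2, 3):
        nt = int((pass_t["charge"] == charge).sum()) if len(pass_t) else 0
        nd = int((pass_d["charge"] == charge).sum()) if len(pass_d) else 0
        per_charge[charge] = ChargeFDR(nt, nd, _fdr(nt, nd))
    total = ChargeFDR(len(pass_t), len(pass_d), _fdr(len(pass_t), len(pass_d)))
    return FDRReport(per_charge, total, histogram, th)


def threshold_search(
    target_psms: pd.DataFrame,
    decoy_psms: pd.DataFrame,
    fdr_goal: float,
    min_spi: float = 70.0,
) -> ThresholdSet:
    """Smallest per-charge integer score cut reaching the FDR goal.

    %SPI is held at ``min_spi``; each charge is searched independently.  If
    the goal is unattainable for a charge, the maximum cut is returned with
    a warning reporting the attained FDR.
    """
    if not 0 < fdr_goal < 1:
        raise ValueError("fdr_goal must be in (0, 1)")
    cuts: dict[int, float] = {}
    for charge in KNOWN_CHARGES:
        t = target_psms[(target_psms["charge"] == charge)
                        & (target_psms["spi"] >= min_spi)]["score"].to_numpy()
        d = decoy_psms[(decoy_psms["charge"] == charge)
                       & (decoy_psms["spi"] >= min_spi)]["score"].to_numpy()
        if len(t) == 0:
            cuts[charge] = 0.0
            continue
        t.sort(); d.sort()
        lo = int(np.floor(min(t.min(), d.min() if len(d) else t.min())))
        hi = int(np.ceil(max(t.max(), d.max() if len(d) else t.max())))
        chosen = None
        last_fdr = math.nan
        for cut in range(lo, hi + 2):
            nt = len(t) - np.searchsorted(t, cut, side="left")
            nd = len(d) - np.searchsorted(d, cut, side="left")
            if nt == 0:
                break
            last_fdr = nd / nt
            if last_fdr <= fdr_goal:
                chosen = cut
                break
        if chosen is None:
            chosen = hi
            logger.warning(
                "FDR goal %.3g unattainable for charge +%d; "
                "max cut %d attains FDR %.3g", fdr_goal, charge, hi, last_fdr)
        cuts[charge] = float(chosen)
    return ThresholdSet(min_score=cuts, min_spi=min_spi)
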