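"""Normalized spectral abundance factor (NSAF) quantitation.

For protein K in one replicate-fraction sample,

    NSAF_K = (SpC_K / MW_K) / sum_I (SpC_I / MW_I)

where SpC is the spectral count (accepted PSMs summed over gel slices) and
MW the molecular weight; the sum runs over the proteins observed in that
sample, so NSAF sums to exactly 1 per sample.  A protein is *quantitated*
in a fraction when observed in at least 3 of the 4 replicates; its mean
NSAF is taken over the observed replicates while the standard deviation
fills missing observations with zeros.  The soluble-minus-membrane NSAF
difference (x1e3, "Diff-NSAF") classifies proteins as predominantly
soluble (green), predominantly membrane (red), evenly distributed
(yellow), or unquantitated (grey).  The module also provides ln-scale
normality/t statistics, per-category NSAF sums, protein abundance ratios,
and an organelle-marker purity estimate anchored on chromogranin A's
assumed ~46% share of vesicle protein.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

FRACTIONS = ("soluble", "membrane")
CLASS_GREEN = "green"
CLASS_RED = "red"
CLASS_YELLOW = "yellow"
CLASS_GREY = "grey"


def count_matrix(
    accepted_psms: pd.DataFrame,
    retained_proteins: Sequence[str],
    fractions: Sequence[str] = FRACTIONS,
    replicates: Sequence[int] = (1, 2, 3, 4),
) -> pd.DataFrame:
    """Spectral counts per retained protein per (fraction, replicate).

    Counts are summed over gel slices.  A PSM whose peptide maps to several
    retained proteins contributes one count to each (flagged in the log);
    a PSM mapping to no retained protein is dropped with a log note.
    """
    retained = sorted(set(retained_proteins))
    cols = pd.MultiIndex.from_product([list(fractions), list(replicates)],
                                      names=["fraction", "replicate"])
    if accepted_psms.empty:
        return pd.DataFrame(0, index=retained, columns=cols)
    psms = accepted_psms
    if "is_decoy" in psms:
        psms = psms[~psms["is_decoy"].astype(bool)]
    ex = psms[["fraction", "replicate"]].assign(
        protein=psms["proteins"].str.split(";")).explode("protein")
    kept = ex[ex["protein"].isin(retained)]
    n_shared = kept.index.value_counts()
    n_shared = int((n_shared > 1).sum())
    if n_shared:
        logger.info("%d PSMs credited to multiple retained proteins", n_shared)
    n_dropped = psms.shape[0] - kept.index.nunique()
    if n_dropped:
        logger.warning("%d accepted PSMs match no retained protein; dropped",
                       n_dropped)
    counts = (kept.groupby(["protein", "fraction", "replicate"])
              .size().unstack(["fraction", "replicate"], fill_value=0))
    return counts.reindex(index=retained, columns=cols, fill_value=0).astype(int)


def nsaf(counts: pd.DataFrame, mw: Mapping[str, float]) -> pd.DataFrame:
    """Per-sample NSAF for a count matrix (columns are samples)."""
    mw_series = pd.Series(mw).reindex(counts.index)
    if (mw_series <= 0).any() or mw_series.isna().any():
        bad = mw_series.index[(mw_series <= 0) | mw_series.isna()]
        raise ValueError(f"non-positive or missing MW for: {list(bad)[:5]}")
    saf = counts.div(mw_series, axis=0)
    totals = saf.sum(axis=0)
    empty = totals == 0
    if empty.any():
        logger.warning("%d all-zero samples; NSAF left at zero for them",
                       int(empty.sum()))
        totals = totals.replace(0, np.nan)
    return saf.div(totals, axis=1).fillna(0.0)


@dataclass
class FractionSummary:
    """Mean/SD NSAF per protein for one fraction (or the pooled total)."""

    n_obs: pd.Series
    mean: pd.Series
    sd: pd.Series
    quantitated: pd.Series


def summarize_fraction(
    counts: pd.DataFrame,
    nsaf_values: pd.DataFrame,
    min_obs: int = 3,
) -> FractionSummary:
    """Apply the replicate rule to one fraction's replicate columns.

    Observation means a nonzero count in that replicate; the mean runs over
    observed replicates only, while the SD runs over all replicates with
    zeros standing in for missing observations.
    """
    observed = counts > 0
    n_obs = observed.sum(axis=1)
    mean = nsaf_values.where(observed).mean(axis=1).fillna(0.0)
    sd = nsaf_values.std(axis=1, ddof=1).fillna(0.0)
    return FractionSummary(n_obs, mean, sd, n_obs >= min_obs)


def diff_nsaf(
    mean_soluble: float,
    mean_membrane: float,
    quant_soluble: bool,
    quant_membrane: bool,
    epsilon: float = 0.2,
) -> tuple[float, str]:
    """Scaled soluble-membrane difference and its distribution class.

    diff = (S - M) x 1e3.  Yellow when the relative difference
    |S - M| / (S + M) is below ``epsilon``; green when positive, red when
    negative; grey when the replicate rule failed in both fractions.  An
    unquantitated fraction contributes 0.
    """
    if not (quant_soluble or quant_membrane):
        return math.nan, CLASS_GREY
    s = mean_soluble if quant_soluble else 0.0
    m = mean_membrane if quant_membrane else 0.0
    if s == 0.0 and m == 0.0:
        return 0.0, CLASS_GREY
    diff = (s - m) * 1e3
    if abs(s - m) / (s + m) < epsilon:
        return diff, CLASS_YELLOW
    return diff, CLASS_GREEN if diff > 0 else CLASS_RED


@dataclass
class QuantResult:
    """Counts, per-sample NSAF, and the per-protein summary table."""

    counts: pd.DataFrame          # protein x (fraction, replicate)
    nsaf: pd.DataFrame            # same shape, per-sample NSAF
    total_nsaf: pd.DataFrame      # protein x replicate, pooled fractions
    summary: pd.DataFrame         # one row per protein

    @property
    def quantitated(self) -> pd.Index:
        mask = self.summary[["quantitated_soluble",
                             "quantitated_membrane"]].any(axis=1)
        return self.summary.index[mask]


def quantify(
    accepted_psms: pd.DataFrame,
    retained_proteins: Sequence[str],
    mw: Mapping[str, float],
    fractions: Sequence[str] = FRACTIONS,
    replicates: Sequence[int] = (1, 2, 3, 4),
    min_obs: int = 3,
    epsilon: float = 0.2,
) -> QuantResult:
    """Full quantitation: counts -> NSAF -> replicate rule -> Diff-NSAF.

    Total NSAF is recomputed from counts pooled across fractions per
    replicate (keeping each replicate's normalization exact), not averaged
    from the per-fraction NSAFs.
    """
    counts = count_matrix(accepted_psms, retained_proteins, fractions, replicates)
    nsaf_all = nsaf(counts, mw)
    pooled = counts.T.groupby(level="replicate").sum().T
    total = nsaf(pooled, mw)

    summaries: dict[str, FractionSummary] = {}
    for fraction in fractions:
        summaries[fraction] = summarize_fraction(
            counts[fraction], nsaf_all[fraction], min_obs)
    summaries["total"] = summarize_fraction(pooled, total, min_obs)

    data: dict[str, pd.Series] = {}
    for name, s in summaries.items():
        data[f"n_obs_{name}"] = s.n_obs
        data[f"mean_{name}"] = s.mean
        data[f"sd_{name}"] = s.sd
        data[f"quantitated_{name}"] = s.quantitated
    summary = pd.DataFrame(data)

    diffs, classes = [], []
    for pid, row in summary.iterrows():
        d, c = diff_nsaf(row["mean_soluble"], row["mean_membrane"],
                         bool(row["quantitated_soluble"]),
                         bool(row["quantitated_membrane"]), epsilon)
        diffs.append(d)
        classes.append(c)
    summary["diff_nsaf_scaled"] = diffs
    summary["dist_class"] = classes
    return QuantResult(counts, nsaf_all, total, summary)


@dataclass
class NormalityResult:
    n: int
    dagostino_stat: float
    dagostino_p: float
    shapiro_stat: float
    shapiro_p: float
    degenerate: bool


@dataclass
class LnStatsReport:
    """ln-scale normality checks and the soluble-vs-membrane t-test."""

    soluble: NormalityResult
    membrane: NormalityResult
    total: NormalityResult
    t_stat: float
    t_p: float
    welch: bool


def _normality(values: np.ndarray) -> NormalityResult:
    n = len(values)
    if n < 3:
        return NormalityResult(n, math.nan, math.nan, math.nan, math.nan, False)
    if np.ptp(values) == 0:
        logger.warning("constant data: normality tests degenerate")
        return NormalityResult(n, math.nan, math.nan, math.nan, math.nan, True)
    sh_stat, sh_p = stats.shapiro(values)
    if n >= 8:
        da_stat, da_p = stats.normaltest(values)
    else:
        da_stat, da_p = math.nan, math.nan
    return NormalityResult(n, float(da_stat), float(da_p),
                           float(sh_stat), float(sh_p), False)


def ln_stats(
    soluble: Sequence[float],
    membrane: Sequence[float],
    total: Sequence[float],
    welch: bool = False,
) -> LnStatsReport:
    """Natural-log transform, normality tests, and Student's t-test.

    Non-measurements (zero or missing NSAF) are excluded before the
    transform.  The t-test compares ln soluble vs ln membrane; the
    classical equal-variance form is the default, Welch's behind a flag.
    """
    def clean(v):
        a = np.asarray(v, dtype=float)
        return np.log(a[a > 0])

    ln_s, ln_m, ln_t = clean(soluble), clean(membrane), clean(total)
    if len(ln_s) >= 2 and len(ln_m) >= 2:
        t_stat, t_p = stats.ttest_ind(ln_s, ln_m, equal_var=not welch)
        t_stat, t_p = float(t_stat), float(t_p)
    else:
        t_stat, t_p = math.nan, math.nan
    return LnStatsReport(_normality(ln_s), _normality(ln_m), _normality(ln_t),
                         t_stat, t_p, welch)


def category_summary(
    quant: QuantResult,
    categories: Mapping[str, str],
    fractions: Sequence[str] = FRACTIONS,
) -> pd.DataFrame:
    """Per-category summed NSAF per replicate, with mean and s.e.m.

    For each fraction, member NSAFs of proteins quantitated in that
    fraction are summed per replicate; the mean and standard error of the
    per-replicate sums are reported.  Uncategorized proteins fall into
    "Miscellaneous" with a warning.
    """
    base_cols = ["category", "fraction", "mean_sum_nsaf", "sem"]
    if quant.summary.empty:
        return pd.DataFrame(columns=base_cols)
    cats = pd.Series({p: categories.get(p, "") for p in quant.summary.index})
    missing = cats == ""
    if missing.any():
        logger.warning("%d proteins without category -> Miscellaneous",
                       int(missing.sum()))
        cats[missing] = "Miscellaneous"

    rows = []
    for fraction in fractions:
        quant_mask = quant.summary[f"quantitated_{fraction}"]
        sub = quant.nsaf[fraction].loc[quant_mask[quant_mask].index]
        sums = sub.groupby(cats.reindex(sub.index)).sum()
        for category in sorted(cats.unique()):
            if category in sums.index:
                per_rep = sums.loc[category].to_numpy(dtype=float)
            else:
                per_rep = np.zeros(quant.nsaf[fraction].shape[1])
            n = len(per_rep)
            sem = float(np.std(per_rep, ddof=1) / math.sqrt(n)) if n > 1 else 0.0
            rows.append({
                "category": category, "fraction": fraction,
                "mean_sum_nsaf": float(per_rep.mean()), "sem": sem,
                **{f"rep{i + 1}_sum": float(v) for i, v in enumerate(per_rep)},
            })
    return pd.DataFrame(rows)


def abundance_ratio(
    mean_total_nsaf: Mapping[str, float],
    numerator_id: str,
    denominator_id: str,
) -> float:
    """Ratio of two proteins' mean total NSAFs (NaN when undefined)."""
    num = mean_total_nsaf.get(numerator_id)
    den = mean_total_nsaf.get(denominator_id)
    if num is None or den is None or not den:
        logger.warning("abundance ratio %s/%s undefined",
                       numerator_id, denominator_id)
        return math.nan
    return num / den


@dataclass
class PurityReport:
    """Marker-based contamination estimates and the residual purity."""

    contamination: pd.DataFrame  # marker, organelle, contamination_pct
    purity_pct: float
    cga_id: str
    cga_fraction: float


def purity_estimate(
    mean_total_nsaf: Mapping[str, float],
    markers: Mapping[str, str],
    cga_id: str,
    cga_fraction: float = 46.0,
) -> PurityReport:
    """Contamination from organelle markers, anchored on chromogranin A.

    contamination%(marker) = (NSAF_marker / NSAF_CgA) x cga_fraction, using
    the assumption that chromogranin A composes ~``cga_fraction``% of
    vesicle protein.  Purity = 100 - sum of contaminations, floored at 0.
    Markers without a quantitated NSAF contribute 0.
    """
    cga = mean_total_nsaf.get(cga_id)
    if not cga:
        raise ValueError(f"anchor protein {cga_id!r} is not quantitated")
    rows = []
    for marker, organelle in sorted(markers.items()):
        value = mean_total_nsaf.get(marker, 0.0) or 0.0
        rows.append({"marker": marker, "organelle": organelle,
                     "contamination_pct": value / cga * cga_fraction})
    table = pd.DataFrame(rows,
                         columns=["marker", "organelle", "contamination_pct"])
    purity = max(0.0, 100.0 - table["contamination_pct"].sum())
    return PurityReport(table, purity, cga_id, cga_fraction)
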