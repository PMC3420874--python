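"""End-to-end pipeline: simulate/load -> filter -> infer -> quantify -> annotate.

Chains the analysis stages in experiment order and writes a directory of
TSV outputs plus a ``summary.json`` mirroring the headline inventory of
such a study (identified and quantitated protein counts per fraction,
per-charge FDRs, category sums, marker-based purity).  Every file is
written atomically and all randomness flows from the single configured
seed, so a fixed configuration reproduces byte-identical output.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import io as vio
from .identification import ThresholdSet, apply_thresholds, compute_fdr
from .inference import cluster_proteins, evidence_from_psms, minimal_protein_set
from .network import kinase_partition, node_attributes, read_edges
from .quantitation import (category_summary, ln_stats, purity_estimate,
                           quantify)
from .synthetic import SyntheticConfig, simulate

logger = logging.getLogger(__name__)

_SYNTH_INT_FIELDS = {"n_proteins", "n_isoform_clusters", "mean_seq_len",
                     "n_replicates", "n_slices", "depth", "seed",
                     "detect_min_len", "detect_max_len", "database_excess"}
_SYNTH_FLOAT_FIELDS = {"decoy_ratio", "target_score_mean", "target_score_sd",
                       "decoy_score_mean", "decoy_score_sd", "charge3_shift",
                       "dynamic_range", "isoform_mutation_rate", "slice_spill"}


def synthetic_config_from_flat(flat: dict[str, str],
                               strict: bool = True) -> SyntheticConfig:
    """Build a :class:`SyntheticConfig` from a flat key-value mapping."""
    kwargs: dict = {}
    for key, value in flat.items():
        if key in _SYNTH_INT_FIELDS:
            kwargs[key] = int(value)
        elif key in _SYNTH_FLOAT_FIELDS:
            kwargs[key] = float(value)
        elif key == "cga_like":
            kwargs[key] = value.lower() in ("1", "true", "yes")
        elif key == "charge_probs":
            kwargs[key] = tuple(float(v) for v in value.split(","))
        elif strict:
            raise ValueError(f"unknown simulation config key: {key!r}")
    return SyntheticConfig(**kwargs)


@dataclass
class PipelineConfig:
    """Inputs, thresholds and tuning knobs for a full pipeline run."""

    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    psms_path: str = ""
    fasta_path: str = ""
    categories_path: str = ""
    markers_path: str = ""
    edges_path: str = ""
    thresholds: ThresholdSet = field(default_factory=ThresholdSet)
    min_obs: int = 3
    epsilon: float = 0.2
    cga_id: str = ""
    cga_fraction: float = 46.0
    seeds_a: tuple[str, ...] = ()
    seeds_b: tuple[str, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.epsilon < 1:
            raise ValueError("epsilon must be in [0, 1)")
        if self.min_obs < 1:
            raise ValueError("min_obs must be >= 1")
        if not 0 < self.cga_fraction <= 100:
            raise ValueError("cga_fraction must be in (0, 100]")

    @classmethod
    def from_flat(cls, flat: dict[str, str]) -> "PipelineConfig":
        flat = dict(flat)
        own_str = {"psms_path", "fasta_path", "categories_path",
                   "markers_path", "edges_path", "cga_id"}
        kwargs: dict = {}
        scores = dict(ThresholdSet().min_score)
        th_kwargs: dict = {}
        for key in list(flat):
            value = flat[key]
            if key in own_str:
                kwargs[key] = value
            elif key in ("min_obs",):
                kwargs[key] = int(value)
            elif key in ("epsilon", "cga_fraction"):
                kwargs[key] = float(value)
            elif key in ("seeds_a", "seeds_b"):
                kwargs[key] = tuple(v.strip() for v in value.split(",") if v.strip())
            elif key in ("score_plus1", "score_plus2", "score_plus3"):
                scores[int(key[-1])] = float(value)
            elif key in ("min_spi", "rescue_score", "rescue_spi"):
                th_kwargs[key] = float(value)
            elif key == "rescue_min_peptides":
                th_kwargs[key] = int(value)
            elif key in _SYNTH_INT_FIELDS | _SYNTH_FLOAT_FIELDS | {
                    "cga_like", "charge_probs"}:
                continue  # handled by synthetic_config_from_flat below
            else:
                raise ValueError(f"unknown pipeline config key: {key!r}")
        synth = synthetic_config_from_flat(flat, strict=False)
        kwargs["synthetic"] = synth
        kwargs["seed"] = synth.seed
        kwargs["thresholds"] = ThresholdSet(min_score=scores, **th_kwargs)
        return cls(**kwargs)


def _jsonable(obj):
    if isinstance(obj, float) and math.isnan(obj):
        return None
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, err: Exception):
        super().__init__(f"[{stage}] {err}")
        self.stage = stage


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Execute all stages and write the report bundle to ``out_dir``.

    Returns the summary dictionary that is also written as
    ``summary.json``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # --- simulate or load -------------------------------------------------
    try:
        if config.psms_path:
            psms = vio.read_psms(config.psms_path)
            proteins = vio.read_fasta(config.fasta_path)
            targets = [p for p in proteins if not p.is_decoy]
            truth = None
        else:
            synth = dataclasses.replace(config.synthetic, seed=config.seed)
            sim = simulate(synth)
            targets, truth, psms = sim.proteins, sim.truth, sim.psms
            vio.write_fasta(sim.proteins, out / "target.fasta")
            vio.write_fasta(sim.decoys, out / "decoy.fasta")
            vio.write_truth(truth, out / "truth.tsv")
            vio.write_psms(psms, out / "psms.tsv")
    except Exception as err:  # noqa: BLE001 - stage-tagged abort
        raise StageError("simulate", err) from err

    fractions = tuple(config.synthetic.fractions)
    replicates = tuple(range(1, config.synthetic.n_replicates + 1))

    # --- filter -----------------------------------------------------------
    try:
        result = apply_thresholds(psms, config.thresholds)
        accepted = result.target
        fdr = compute_fdr(psms[~psms["is_decoy"]], psms[psms["is_decoy"]],
                          config.thresholds)
        vio.write_psms(accepted, out / "accepted_psms.tsv")
        vio.write_table(fdr.to_frame(), out / "fdr.tsv")
        vio.write_table(fdr.histogram, out / "fdr_histogram.tsv")
    except Exception as err:
        raise StageError("filter", err) from err

    # --- infer ------------------------------------------------------------
    try:
        clusters = cluster_proteins(targets)
        evidence = evidence_from_psms(accepted)
        retained = minimal_protein_set(evidence, clusters) if evidence else set()
        vio.write_table(clusters.to_frame(), out / "clusters.tsv")
        vio.write_table(pd.DataFrame({"protein": sorted(retained)}),
                        out / "retained_proteins.tsv")
    except Exception as err:
        raise StageError("infer", err) from err

    # --- quantify ---------------------------------------------------------
    try:
        mw = {p.id: p.mw for p in targets}
        quant = quantify(accepted, sorted(retained), mw, fractions,
                         replicates, config.min_obs, config.epsilon)
        if config.categories_path:
            categories = vio.read_mapping(config.categories_path,
                                          "protein", "category")
        else:
            categories = {p.id: p.category for p in targets if p.category}
        cats = category_summary(quant, categories, fractions)
        stats_report = ln_stats(
            quant.summary.loc[quant.summary["quantitated_soluble"],
                              "mean_soluble"],
            quant.summary.loc[quant.summary["quantitated_membrane"],
                              "mean_membrane"],
            quant.summary.loc[quant.summary["quantitated_total"],
                              "mean_total"])
        flat_quant = quant.summary.copy()
        flat_quant.insert(0, "protein", flat_quant.index)
        vio.write_table(flat_quant, out / "quant.tsv")
        vio.write_table(cats, out / "categories.tsv")
    except Exception as err:
        raise StageError("quantify", err) from err

    # --- purity -----------------------------------------------------------
    purity = None
    try:
        markers: dict[str, str] = {}
        cga_id = config.cga_id
        if config.markers_path:
            markers = vio.read_mapping(config.markers_path,
                                       "protein", "organelle")
        elif truth is not None:
            tab = truth.table
            markers = dict(zip(
                tab.loc[(tab["marker"] != "") & (tab["marker"] != "dcsv"),
                        "protein_id"],
                tab.loc[(tab["marker"] != "") & (tab["marker"] != "dcsv"),
                        "marker"]))
            if not cga_id:
                hits = tab.loc[tab["marker"] == "dcsv", "protein_id"]
                cga_id = hits.iloc[0] if len(hits) else ""
        if cga_id and markers:
            mean_total = quant.summary["mean_total"].to_dict()
            purity = purity_estimate(mean_total, markers, cga_id,
                                     config.cga_fraction)
            vio.write_table(purity.contamination, out / "purity.tsv")
    except Exception as err:
        raise StageError("purity", err) from err

    # --- annotate ---------------------------------------------------------
    try:
        symbols = {p.id: p.symbol for p in targets if p.symbol}
        attrs = node_attributes(quant, symbols,
                                {p.id: p.category for p in targets})
        vio.write_table(attrs, out / "node_attributes.tsv")
        partition = None
        if config.edges_path:
            graph = read_edges(config.edges_path)
            if config.seeds_a or config.seeds_b:
                a_only, b_only, both = kinase_partition(
                    graph, config.seeds_a, config.seeds_b)
                partition = {"a_only": sorted(a_only),
                             "b_only": sorted(b_only),
                             "both": sorted(both)}
                vio.write_table(
                    pd.DataFrame(
                        [(s, grp) for grp, ss in partition.items() for s in ss],
                        columns=["symbol", "group"]),
                    out / "kinase_partition.tsv")
    except Exception as err:
        raise StageError("annotate", err) from err

    # --- summary ----------------------------------------------------------
    identified = {
        f: int((quant.counts[f].sum(axis=1) > 0).sum()) for f in fractions
    }
    summary = {
        "seed": config.seed,
        "n_psms_input": int(len(psms)),
        "n_psms_accepted": int(len(accepted)),
        "n_proteins_retained": len(retained),
        "n_identified": {**identified, "total": len(retained)},
        "n_quantitated": int(len(quant.quantitated)),
        "fdr": {
            "plus2": fdr.per_charge[2].fdr,
            "plus3": fdr.per_charge[3].fdr,
            "total": fdr.total.fdr,
        },
        "purity_pct": purity.purity_pct if purity else None,
        "ln_soluble_vs_membrane_t_p": stats_report.t_p,
        "categories": {
            row["category"]: round(row["mean_sum_nsaf"], 6)
            for _, row in cats[cats["fraction"] == fractions[0]].iterrows()
        },
        "kinase_partition": partition,
    }
    with vio.atomic_write(out / "summary.json") as tmp:
        tmp.write_text(json.dumps(_jsonable(summary), indent=2,
                                  sort_keys=True, allow_nan=False) + "\n")
    logger.info("pipeline complete: %d retained, %d quantitated",
                len(retained), summary["n_quantitated"])
    return summary
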