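# vesiquant

Label-free spectral-count quantitation for organelle proteomes measured by
GeLC-MS/MS — written for the dense-core secretory vesicle (chromaffin
granule) setting, where a purified vesicle preparation is split into
soluble and membrane fractions, run as four replicate SDS-PAGE lanes of
eight gel slices each, and searched against a protein database with a
shuffled-decoy companion.

The package is for proteomics analysts who have search-engine PSM exports
(or want a fully synthetic, ground-truthed stand-in) and need the complete
chain from PSM filtering to network-ready abundance annotations:

* **Identification** — per-charge score/%SPI thresholds (score ≥13,
  %SPI ≥70 for +1/+2; score ≥16 for +3), a two-peptide rescue rule
  (score ≥10, %SPI ≥70), and decoy-based FDR with width-1 score
  histograms: `FDR = decoy identifications / real identifications`.
* **Protein inference** — single-linkage clustering of the database at
  ≥95% identity over ≥90% of the shorter sequence, then the smallest
  minimally-redundant protein set explaining every accepted peptide
  (isoforms admitted only when unique peptides require them).
* **Quantitation** — the normalized spectral abundance factor per
  replicate-fraction sample,

  ```
  NSAF_K = (SpC_K / MW_K) / Σ_I (SpC_I / MW_I)
  ```

  with the 3-of-4 replicate rule, zero-filled standard deviations,
  ln-scale normality and t statistics, Diff-NSAF = (S − M)×10³ with the
  green/red/yellow/grey distribution classes, per-category NSAF sums,
  abundance ratios, and a chromogranin-A-anchored purity estimate
  (`contamination% = NSAF_marker / NSAF_CgA × 46`).
* **Network annotation** — node-attribute tables for Cytoscape-style
  tools and kinase-neighborhood partitions (e.g. PKA-only / PKC-only /
  shared interactors) over TSV or SIF edge lists.
* **Synthetic data** — a generator that emulates the whole design
  (isoform clusters, log-uniform abundances over ~10⁵, fraction
  propensities, MW-banded slices, target/decoy score separation,
  replicate dropout, database excess) with per-protein ground truth for
  recovery testing.

## Worked example

```python
import vesiquant as vq

# Published prohormone-processing abundances (mean NSAF x 1e3) ship with
# the package; abundance ratios reproduce the reported ~3 and ~6:
table = vq.prohormone_abundances()["mean_nsaf_x1000"].to_dict()
print("PC2 : PC1/3  =", round(vq.abundance_ratio(table, "PC2", "PC1_3"), 2))
print("CPE : PC1/3  =", round(vq.abundance_ratio(table, "CPE", "PC1_3"), 2))

# Full synthetic pipeline: simulate -> filter -> infer -> quantify -> annotate
cfg = vq.PipelineConfig(
    synthetic=vq.SyntheticConfig(depth=10_000, seed=42), seed=42)
summary = vq.run_pipeline(cfg, "report")
print("accepted PSMs :", summary["n_psms_accepted"])
print("retained      :", summary["n_proteins_retained"])
print("quantitated   :", summary["n_quantitated"])
print("FDR total     :", round(summary["fdr"]["total"], 5))
print("purity (%)    :", round(summary["purity_pct"], 1))
```

prints

```
PC2 : PC1/3  = 3.12
CPE : PC1/3  = 6.04
accepted PSMs : 64377
retained      : 241
quantitated   : 87
FDR total     : 0.00046
purity (%)    : 98.3
```

The ratios say prohormone convertase 2 and carboxypeptidase E are ~3× and
~6× more abundant than PC1/3. The pipeline run accepted ~64k of 120k
simulated PSMs, retained 241 proteins as the minimal set explaining them
(150 truly present plus background entries rescued by chance two-peptide
support — these end up in the grey, unquantitated class), quantitated 87
in ≥3 of 4 replicates, estimated a 0.05% PSM-level FDR from the decoys,
and put the vesicle purity near 98% from the three planted organelle
markers. The report directory holds the FASTA, PSM, FDR, cluster, quant,
category, purity and node-attribute tables plus `summary.json`.

The same stages are available from the shell:

```sh
vesiquant simulate --config sim.cfg --out-dir sim/
vesiquant filter --psms sim/psms.tsv --report filtered/
vesiquant infer --psms filtered/accepted_psms.tsv --fasta sim/target.fasta --out inferred/
vesiquant quantify --psms filtered/accepted_psms.tsv \
    --proteins inferred/retained_proteins.tsv --fasta sim/target.fasta --out quant/
vesiquant report --config sim.cfg --out-dir report/   # everything at once
```

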