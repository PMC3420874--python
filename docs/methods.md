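# Methods

## Scope and model

`vesiquant` implements label-free spectral-count quantitation for an
organelle proteome measured by GeLC-MS/MS: two biochemical fractions
(soluble and membrane) of a purified vesicle preparation, each run as four
replicate SDS-PAGE lanes cut into eight molecular-weight slices. The
analysis chain is

1. **PSM filtering** — per-charge score/%SPI thresholds (score ≥13 and
   %SPI ≥70 for +1/+2 precursors, score ≥16 for +3), with a rescue rule
   that admits PSMs at score ≥10/%SPI ≥70 when the protein carries two or
   more distinct peptides across the accepted-plus-candidate pool.
2. **Decoy FDR** — decoy matches from a twice-shuffled copy of the search
   database, score histograms in width-1 bins, and
   FDR = decoy identifications / real identifications at the threshold
   set, per charge and overall.
3. **Protein inference** — single-linkage clustering of the database at
   ≥95% alignment identity over ≥90% of the shorter sequence, then the
   smallest protein set explaining every accepted peptide, admitting
   isoforms only when unique peptides require them.
4. **NSAF quantitation** — per replicate-fraction sample,
   `NSAF_K = (SpC_K/MW_K) / Σ_I (SpC_I/MW_I)`; a protein is quantitated in
   a fraction when observed in ≥3 of 4 replicates; means run over observed
   replicates, standard deviations over all four with zeros for missing
   observations; total NSAF is recomputed from counts pooled across
   fractions per replicate, which keeps each normalization exact.
5. **Distribution mapping** — Diff-NSAF = (soluble − membrane) × 10³;
   classes green (soluble), red (membrane), yellow (evenly distributed),
   grey (identified but unquantitated).
6. **Purity** — contamination%(marker) = (NSAF_marker / NSAF_CgA) × 46,
   anchored on the assumption that chromogranin A composes ~46% of vesicle
   protein; purity = 100 − Σ contamination, floored at 0.
7. **Network annotation** — node-attribute export with the Diff-NSAF color
   scheme and a seed-neighborhood partition (e.g. PKA-only / PKC-only /
   shared interactors) over a user-supplied edge list.

## Synthetic data generator

The generator is first-class, tested code; it defines the statistical
structure every downstream stage assumes.

* **Proteome.** `n_proteins` sequences partitioned into
  `n_isoform_clusters` clusters; within a cluster, members are the cluster
  base with point substitutions at 2% of positions, so any two members
  share ≥96% identity over their full common length and planted clusters
  sit safely above the 95%/90% edge threshold (at 5% mutation two
  co-members could fall to 90% identity and the planted partition would
  not be recoverable even in principle). Molar abundances are log-uniform
  over `[1, 1e5]`, matching a mass-spectrometric dynamic range of a few
  times 10⁵. Molecular weight uses average residue masses plus one water
  (Biopython); NSAF only needs a consistent size proxy.
* **Anchor and markers.** By default one singleton protein is pinned to
  ~46% of total molar abundance (the chromogranin-A-like matrix anchor)
  and three contaminant markers (lysosomal, 2× mitochondrial) are pinned
  to 0.3/0.2/0.6% relative abundance, emulating a highly pure vesicle
  preparation whose purity estimate should come out near 99%.
* **Search-database excess.** The database holds `database_excess` (=50)
  entries per truly present protein; background entries are never sampled
  but receive random mis-assignments. This matters: if false matches
  could only land on the ~200 present proteins, every zero-abundance
  protein would accumulate a noise floor large enough to be "quantitated"
  from noise alone, which is not how false matches behave against a
  full-organism database.
* **Counts.** For each replicate × fraction, expected counts are
  proportional to molar abundance × number of detectable tryptic peptides
  (7–30 residues), split between fractions by the protein's soluble
  propensity θ; a protein drops out of a sample with probability
  `exp(−E[count])` before counts are drawn from a multinomial at the
  configured depth (10⁴ per sample by default, 10⁵ in recovery checks).
  Slices follow eight equal-probability MW bands with 10% spill-over to
  adjacent bands.
* **Scores.** True matches draw scores from N(20, 4²), null matches
  (decoy and mis-assigned) from N(8, 2²), both shifted +2 for +3
  precursors and truncated at 0, which places the 13/16 thresholds between
  the modes; %SPI is Beta(8,2)×100 for true matches and uniform for null
  matches. Decoy PSMs are injected at `decoy_ratio` × depth per sample,
  together with an equal number of mis-assigned target PSMs (labelled
  `is_noise`) modelling random matches against an equal-size target
  database — this is what makes the decoy FDR estimate checkable against
  a realized false-match fraction.

What the generator does **not** emulate: spectrum-level detail (m/z,
retention time), peptide-specific detectability/ionization efficiency,
shared peptides between unrelated proteins beyond chance, correlated
replicate effects, and real decoy-score tails. Passing tests therefore
demonstrate the correctness and calibration of the analysis chain under
its own model assumptions, not instrument-level realism.

## Numerical and design choices

* **FDR at primary thresholds.** The decoy FDR is a peptide-level
  estimate at the per-charge score/%SPI cuts. The two-peptide rescue is a
  protein-level identification criterion applied separately; including
  rescued PSMs in the FDR ratio would compare decoy matches (no peptide
  support) against noise matches riding on real proteins' support and
  systematically understate the false fraction.
* **Alignment identity.** Pairwise identity uses a global alignment with
  match +1, mismatch 0; gaps carry an infinitesimal (−10⁻⁶) penalty purely
  as a tie-break, so the match count is the alignment score and the
  traceback deterministically picks the fewest-gap optimum among the
  otherwise wildly degenerate zero-gap optima. Identity divides identical
  positions by alignment columns excluding terminal gaps; coverage divides
  the aligned span on the shorter sequence by its length (the shorter-
  sequence convention resolves the ambiguity in "90% of the sequence
  length"). An inverted 8-mer index prescreens candidate pairs: ≤5%
  non-identical columns forces a common identical run of ~19 residues, so
  any qualifying pair of sequences longer than ~40 shares an 8-mer.
* **Minimal protein set.** Unique-peptide proteins are forced in,
  dominated candidates eliminated, and the residual set cover is solved
  exactly by branch and bound when ≤22 candidates remain (greedy with an
  irredundancy pruning pass beyond that). Exact solution honours the
  "smallest" set claim and is what the exhaustive-enumeration checks
  verify; ties prefer cluster representatives, then longer sequences, then
  lexicographically smaller ids, which keeps the output deterministic and
  admits isoforms only when required.
* **Shared peptides.** A PSM whose peptide maps to several retained
  proteins credits one count to each (logged). Distributive NSAF is out of
  scope; parsimony makes such peptides rare.
* **Yellow band.** "Evenly distributed" has no published numeric cutoff;
  the default is a relative difference |S−M|/(S+M) < 0.2, configurable.
* **Statistics.** Normality checks are D'Agostino–Pearson (n ≥ 8) and
  Shapiro–Wilk (n ≥ 3) on ln-transformed values with non-measurements
  excluded; the soluble-vs-membrane comparison is the classical
  equal-variance two-sample t-test, with Welch's form behind a flag.
  Constant inputs are flagged degenerate rather than tested.
* **Determinism.** All randomness flows from a single seed; protein lists
  are sorted wherever order could leak in, and every output file is
  written atomically (temp-then-rename), so a fixed configuration
  reproduces byte-identical bundles.

## Problem sizes

Recovery checks run at 200 proteins × depth 10⁵ (three seeds in the test
suite, one in the acceptance script); the determinism probe at depth 10⁴;
parsimony exactness on 200 random instances of ≤12 proteins and ≤25
peptides against full subset enumeration. These sizes give stable
statistics (hundreds of thousands of PSMs, tens of θ-extreme proteins)
while a full run of everything stays in the minutes range.

## Known limitations

* Spectral counting saturates for very short or very long proteins when
  the detectable-peptide window truncates; the length correction is only
  as good as the MW proxy.
* The two-peptide rescue rule admits background proteins supported by two
  chance mis-assignments; they surface as identified-but-grey entries, as
  in real searches, and inflate the identified count relative to the
  quantitated count.
* Marker-based purity inherits the ~46% anchor assumption linearly; a
  noise floor on marker counts biases contamination upward slightly
  (purity estimates in synthetic runs land near 98% against a planted
  98.9%).
* No protein-level differential testing or multiple-testing correction is
  provided; the t-test compares the distribution of soluble vs membrane
  NSAF as a whole.
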