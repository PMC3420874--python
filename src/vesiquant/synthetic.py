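"""Synthetic GeLC-MS/MS data generator.

Emulates the study design the downstream analysis assumes: a purified
dense-core secretory-vesicle preparation split into soluble and membrane
fractions, each run in four replicate SDS-PAGE lanes cut into eight
molecular-weight slices, with every slice analysed by LC-MS/MS.  The
generator produces

* a target proteome organised into isoform clusters (members of a cluster
  share >=95% sequence identity so that similarity clustering downstream is
  exercised),
* per-protein ground truth (molar abundance, soluble-fraction propensity,
  organelle-marker labels),
* a decoy proteome built by twice-shuffling each target sequence, and
* a peptide-spectrum-match (PSM) table whose per-protein counts follow a
  multinomial with expectation proportional to abundance x number of
  detectable tryptic peptides, with score/%SPI distributions separated
  between true matches and null (decoy or mis-assigned) matches.

All randomness flows from ``SyntheticConfig.seed``; identical configs give
byte-identical outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .records import STANDARD_AA, ProteinRecord

logger = logging.getLogger(__name__)

PSM_COLUMNS = [
    "peptide", "proteins", "charge", "score", "spi",
    "fraction", "replicate", "slice", "is_decoy", "is_noise",
]

#: marker proteins forced into the proteome when ``cga_like`` is set:
#: (symbol, organelle, relative abundance as % of the granule-matrix anchor
#: protein scaled by its assumed 46% share of total protein)
_CONTAMINANTS = (
    ("GUSB", "lysosome", 0.3),
    ("CS", "mitochondria", 0.2),
    ("FH", "mitochondria", 0.6),
)

_CATEGORIES = (
    "Neurotransmitters and hormones",
    "Biochemical processing",
    "Internal vesicle conditions",
    "Secretory mechanisms",
    "Structural elements",
    "Signaling and regulation",
    "Miscellaneous",
)


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the simulated experiment.

    ``depth`` is the expected number of target PSMs per replicate-fraction
    sample; ``decoy_ratio`` scales the number of injected decoy PSMs (and an
    equal number of mis-assigned "noise" target PSMs, modelling random
    matches against an equal-size decoy database).
    """

    n_proteins: int = 150
    n_isoform_clusters: int = 120
    mean_seq_len: int = 300
    fractions: tuple[str, ...] = ("soluble", "membrane")
    n_replicates: int = 4
    n_slices: int = 8
    depth: int = 10_000
    decoy_ratio: float = 0.25
    charge_probs: tuple[float, float, float] = (0.1, 0.6, 0.3)
    seed: int = 0
    # score model: null = decoy/mis-assigned, shared across charges except a
    # +2 shift for +3 precursors (both distributions), truncated at 0
    target_score_mean: float = 20.0
    target_score_sd: float = 4.0
    decoy_score_mean: float = 8.0
    decoy_score_sd: float = 2.0
    charge3_shift: float = 2.0
    dynamic_range: float = 1e5
    isoform_mutation_rate: float = 0.02
    detect_min_len: int = 7
    detect_max_len: int = 30
    slice_spill: float = 0.1
    cga_like: bool = True
    #: search-database entries per true proteome entry: the database holds
    #: (database_excess - 1) * n_proteins background proteins that are never
    #: sampled, so random mis-assignments spread over the database the way
    #: they do against a full organism database
    database_excess: int = 50

    def validate(self) -> None:
        if self.n_proteins < 1:
            raise ValueError("n_proteins must be >= 1")
        if not 1 <= self.n_isoform_clusters <= self.n_proteins:
            raise ValueError(
                "n_isoform_clusters must be between 1 and n_proteins "
                f"(got {self.n_isoform_clusters} for {self.n_proteins} proteins)"
            )
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.depth < 0:
            raise ValueError("depth must be >= 0")
        if abs(sum(self.charge_probs) - 1.0) > 1e-9:
            raise ValueError("charge_probs must sum to 1")
        if self.dynamic_range < 1e4:
            raise ValueError("dynamic_range must span at least 1e4")
        if self.database_excess < 1:
            raise ValueError("database_excess must be >= 1")


@dataclass
class SyntheticTruth:
    """Ground truth for parameter-recovery tests: one row per target protein
    (molar_abundance, theta_soluble, marker organelle label, cluster id)."""

    table: pd.DataFrame

    @property
    def abundance(self) -> pd.Series:
        return self.table.set_index("protein_id")["molar_abundance"]

    @property
    def theta(self) -> pd.Series:
        return self.table.set_index("protein_id")["theta_soluble"]


def tryptic_digest(sequence: str) -> list[str]:
    """Cleave after K or R except when the next residue is P.

    Returns peptides in order; their concatenation equals the input.
    """
    if not sequence:
        raise ValueError("cannot digest an empty sequence")
    peptides: list[str] = []
    start = 0
    for i in range(len(sequence) - 1):
        if sequence[i] in "KR" and sequence[i + 1] != "P":
            peptides.append(sequence[start : i + 1])
            start = i + 1
    peptides.append(sequence[start:])
    return peptides


def detectable_peptides(
    sequence: str, min_len: int = 7, max_len: int = 30
) -> list[str]:
    """Tryptic peptides within the observable length window."""
    return [p for p in tryptic_digest(sequence) if min_len <= len(p) <= max_len]


def generate_proteome(
    config: SyntheticConfig,
) -> tuple[list[ProteinRecord], SyntheticTruth]:
    """Generate target proteins partitioned into isoform clusters plus truth.

    Proteins are split as evenly as possible into ``n_isoform_clusters``
    clusters; within a multi-member cluster every member is the cluster base
    sequence with point substitutions at ``isoform_mutation_rate`` of its
    positions, so any two members share >= (1 - 2*rate) identity over their
    full (equal) length.  Molar abundances are log-uniform over
    ``[1, dynamic_range]``.  When ``cga_like`` is set, one singleton protein
    is pinned to ~46% of total molar abundance (the granule-matrix anchor,
    symbol CHGA) and three contaminant organelle markers are pinned to small
    relative abundances.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n, k = config.n_proteins, config.n_isoform_clusters
    sizes = [n // k + (1 if i < n % k else 0) for i in range(k)]
    aa = np.array(list(STANDARD_AA))

    records: list[ProteinRecord] = []
    rows: list[dict] = []
    idx = 0
    for ci, size in enumerate(sizes):
        length = max(60, int(round(rng.normal(config.mean_seq_len,
                                              0.25 * config.mean_seq_len))))
        base = rng.choice(aa, size=length)
        for m in range(size):
            seq = base.copy()
            if m > 0:
                n_mut = max(1, int(round(config.isoform_mutation_rate * length)))
                pos = rng.choice(length, size=n_mut, replace=False)
                for p in pos:
                    choices = [c for c in STANDARD_AA if c != seq[p]]
                    seq[p] = choices[rng.integers(len(choices))]
            pid = f"SYN{idx:04d}"
            records.append(
                ProteinRecord(
                    id=pid,
                    sequence="".join(seq),
                    symbol=f"GN{idx:04d}",
                    category=_CATEGORIES[rng.integers(len(_CATEGORIES))],
                )
            )
            rows.append({
                "protein_id": pid,
                "molar_abundance": float(10 ** rng.uniform(
                    0, np.log10(config.dynamic_range))),
                "theta_soluble": float(rng.uniform(0.0, 1.0)),
                "marker": "",
                "cluster": ci,
            })
            idx += 1

    truth = pd.DataFrame(rows)
    if config.cga_like and n >= 5:
        singletons = [i for i, s in enumerate(sizes) if s == 1]
        # pick 4 singleton clusters for the anchor + 3 markers; fall back to
        # the last proteins when there are not enough singletons
        if len(singletons) >= 4:
            picks = [int(truth.index[truth["cluster"] == c][0])
                     for c in singletons[-4:]]
        else:
            picks = list(range(n - 4, n))
        cga_row, marker_rows = picks[-1], picks[:-1]
        others = truth["molar_abundance"].drop(index=picks).sum()
        a_cga = others * 0.46 / (1.0 - 0.46)
        truth.loc[cga_row, ["molar_abundance", "theta_soluble", "marker"]] = (
            a_cga, 0.95, "dcsv")
        records[cga_row].symbol = "CHGA"
        records[cga_row].category = _CATEGORIES[0]
        for row, (sym, organelle, pct) in zip(marker_rows, _CONTAMINANTS):
            truth.loc[row, ["molar_abundance", "marker"]] = (
                pct / 46.0 * a_cga, organelle)
            records[row].symbol = sym
            records[row].category = _CATEGORIES[-1]

    # background database entries: present in the search database, absent
    # from the sample (no truth rows), the landing space for random matches
    n_background = (config.database_excess - 1) * n
    for b in range(n_background):
        length = max(60, int(round(rng.normal(config.mean_seq_len,
                                              0.25 * config.mean_seq_len))))
        records.append(
            ProteinRecord(
                id=f"BGD{b:05d}",
                sequence="".join(rng.choice(aa, size=length)),
                symbol=f"GB{b:05d}",
                category=_CATEGORIES[rng.integers(len(_CATEGORIES))],
            )
        )

    return records, SyntheticTruth(truth)


def shuffle_decoy(
    proteins: Sequence[ProteinRecord], seed: int = 0
) -> list[ProteinRecord]:
    """One decoy per target, built by two independent shuffling passes.

    Residue composition and length (hence MW) are preserved; decoy ids and
    symbols are prefixed ``DECOY_``.
    """
    if not proteins:
        raise ValueError("cannot build decoys from an empty target list")
    rng = np.random.default_rng(seed)
    decoys = []
    for rec in proteins:
        chars = np.array(list(rec.sequence))
        chars = chars[rng.permutation(len(chars))]
        chars = chars[rng.permutation(len(chars))]
        decoys.append(
            ProteinRecord(
                id=f"DECOY_{rec.id}",
                sequence="".join(chars),
                symbol=f"DECOY_{rec.symbol}",
                category=rec.category,
                is_decoy=True,
                mw=rec.mw,
            )
        )
    return decoys


def _mw_bands(mw: np.ndarray, n_slices: int) -> np.ndarray:
    """Quantile edges splitting proteins into equal-probability MW bands."""
    qs = np.linspace(0, 1, n_slices + 1)[1:-1]
    return np.quantile(mw, qs)


def _peptide_flat(peplists: list[list[str]]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    flat = np.array([p for pl in peplists for p in pl], dtype=object)
    npep = np.array([len(pl) for pl in peplists], dtype=np.int64)
    offsets = np.concatenate([[0], np.cumsum(npep)[:-1]])
    return flat, offsets, npep


def generate_psms(
    proteins: Sequence[ProteinRecord],
    truth: SyntheticTruth,
    config: SyntheticConfig,
) -> pd.DataFrame:
    """Simulate the PSM export of a database search over the whole design.

    For every replicate x fraction sample the expected count of a protein is
    ``depth * abundance * n_detectable_peptides * theta`` (normalised), where
    theta is the soluble propensity (or its complement for the membrane
    fraction).  A protein drops out of a sample with probability
    ``exp(-E[count])`` before counts are drawn multinomially, which produces
    realistic missingness across replicates.  Each PSM carries a peptide
    drawn uniformly from the protein's detectable peptides and lists every
    target protein containing that peptide.  Decoy PSMs (``decoy_ratio *
    depth`` per sample) and an equal number of mis-assigned target PSMs
    (``is_noise``) draw their scores from the null distribution.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    targets = [p for p in proteins if not p.is_decoy]
    decoys = [p for p in proteins if p.is_decoy]
    if config.decoy_ratio > 0 and not decoys:
        decoys = shuffle_decoy(targets, seed=config.seed + 1)

    peplists = [detectable_peptides(p.sequence, config.detect_min_len,
                                    config.detect_max_len) for p in targets]
    pep_flat, offsets, npep = _peptide_flat(peplists)
    owners: dict[str, set[str]] = {}
    for p, pl in zip(targets, peplists):
        for pep in set(pl):
            owners.setdefault(pep, set()).add(p.id)
    owner_str = {pep: ";".join(sorted(ids)) for pep, ids in owners.items()}

    # background database entries have no truth row -> zero sampling weight
    abundance = (truth.abundance.reindex([p.id for p in targets])
                 .fillna(0.0).to_numpy())
    theta = (truth.theta.reindex([p.id for p in targets])
             .fillna(0.5).to_numpy())
    weight = abundance * npep

    mw = np.array([p.mw for p in targets])
    edges = _mw_bands(mw, config.n_slices)
    band = np.searchsorted(edges, mw)

    d_peplists = [detectable_peptides(p.sequence, config.detect_min_len,
                                      config.detect_max_len) for p in decoys]
    d_keep = [i for i, pl in enumerate(d_peplists) if pl]
    d_flat, d_offsets, d_npep = _peptide_flat([d_peplists[i] for i in d_keep])
    d_ids = np.array([decoys[i].id for i in d_keep], dtype=object)
    d_band = np.searchsorted(edges, np.array([decoys[i].mw for i in d_keep])) \
        if d_keep else np.array([], dtype=np.int64)
    noise_pool = np.flatnonzero(npep > 0)

    charges = np.array([1, 2, 3])
    spill = config.slice_spill
    frames: list[pd.DataFrame] = []

    def _slice_of(bands: np.ndarray) -> np.ndarray:
        off = rng.choice([-1, 0, 1], size=len(bands),
                         p=[spill, 1 - 2 * spill, spill])
        return np.clip(bands + off, 0, config.n_slices - 1) + 1

    def _scores(m: int, mean: float, sd: float, charge: np.ndarray) -> np.ndarray:
        s = rng.normal(mean, sd, m) + config.charge3_shift * (charge == 3)
        return np.clip(s, 0.0, None)

    for fraction in config.fractions:
        prop = theta if fraction == "soluble" else 1.0 - theta
        fw = weight * prop
        for rep in range(1, config.n_replicates + 1):
            total = fw.sum()
            if total > 0 and config.depth > 0:
                expect = config.depth * fw / total
                dropped = rng.random(len(fw)) < np.exp(-expect)
                kept = fw * ~dropped
                if kept.sum() > 0:
                    counts = rng.multinomial(config.depth, kept / kept.sum())
                else:
                    counts = np.zeros(len(fw), dtype=np.int64)
            else:
                counts = np.zeros(len(fw), dtype=np.int64)

            pidx = np.repeat(np.arange(len(fw)), counts)
            m = len(pidx)
            charge = rng.choice(charges, size=m, p=config.charge_probs)
            pep = pep_flat[offsets[pidx] + rng.integers(0, npep[pidx])] \
                if m else np.array([], dtype=object)
            tgt = pd.DataFrame({
                "peptide": pep,
                "proteins": pd.Series(pep, dtype=object).map(owner_str)
                if m else pd.Series([], dtype=object),
                "charge": charge,
                "score": _scores(m, config.target_score_mean,
                                 config.target_score_sd, charge),
                "spi": 100.0 * rng.beta(8, 2, m),
                "fraction": fraction,
                "replicate": rep,
                "slice": _slice_of(band[pidx]),
                "is_decoy": False,
                "is_noise": False,
            })
            frames.append(tgt)

            n_null = int(round(config.decoy_ratio * config.depth))
            if n_null and len(d_ids):
                di = rng.integers(0, len(d_ids), n_null)
                dch = rng.choice(charges, size=n_null, p=config.charge_probs)
                dpep = d_flat[d_offsets[di] + rng.integers(0, d_npep[di])]
                frames.append(pd.DataFrame({
                    "peptide": dpep,
                    "proteins": d_ids[di],
                    "charge": dch,
                    "score": _scores(n_null, config.decoy_score_mean,
                                     config.decoy_score_sd, dch),
                    "spi": rng.uniform(0, 100, n_null),
                    "fraction": fraction,
                    "replicate": rep,
                    "slice": _slice_of(d_band[di]),
                    "is_decoy": True,
                    "is_noise": False,
                }))
            if n_null and len(noise_pool):
                ni = noise_pool[rng.integers(0, len(noise_pool), n_null)]
                nch = rng.choice(charges, size=n_null, p=config.charge_probs)
                npp = pep_flat[offsets[ni] + rng.integers(0, npep[ni])]
                frames.append(pd.DataFrame({
                    "peptide": npp,
                    "proteins": pd.Series(npp, dtype=object).map(owner_str),
                    "charge": nch,
                    "score": _scores(n_null, config.decoy_score_mean,
                                     config.decoy_score_sd, nch),
                    "spi": rng.uniform(0, 100, n_null),
                    "fraction": fraction,
                    "replicate": rep,
                    "slice": _slice_of(band[ni]),
                    "is_decoy": False,
                    "is_noise": True,
                }))

    if not frames:
        return pd.DataFrame(columns=PSM_COLUMNS)
    psms = pd.concat(frames, ignore_index=True)
    if psms.empty:
        return pd.DataFrame(columns=PSM_COLUMNS)
    return psms[PSM_COLUMNS]


@dataclass
class SimulationResult:
    proteins: list[ProteinRecord]
    decoys: list[ProteinRecord]
    truth: SyntheticTruth
    psms: pd.DataFrame

    @property
    def all_records(self) -> list[ProteinRecord]:
        return self.proteins + self.decoys


def simulate(config: SyntheticConfig) -> SimulationResult:
    """Full simulation: proteome + decoys + truth + PSM table."""
    proteins, truth = generate_proteome(config)
    decoys = shuffle_decoy(proteins, seed=config.seed + 1)
    psms = generate_psms(proteins + decoys, truth, config)
    logger.info("simulated %d PSMs for %d proteins (seed=%d)",
                len(psms), len(proteins), config.seed)
    return SimulationResult(proteins, decoys, truth, psms)
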