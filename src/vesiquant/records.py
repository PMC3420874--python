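"""Shared record types for protein database entries."""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio.SeqUtils import molecular_weight

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"


def protein_mw(sequence: str) -> float:
    """Average (not monoisotopic) molecular weight of a protein sequence, in Da.

    Sum of average residue masses plus one water, as computed by Biopython.
    Raises ``ValueError`` on residues outside the 20 standard amino acids.
    """
    bad = set(sequence) - set(STANDARD_AA)
    if bad:
        raise ValueError(f"non-standard residues in sequence: {sorted(bad)}")
    return float(molecular_weight(sequence, seq_type="protein"))


@dataclass
class ProteinRecord:
    """One protein database entry (target or decoy)."""

    id: str
    sequence: str
    symbol: str = ""
    category: str = ""
    is_decoy: bool = False
    mw: float = field(default=0.0)

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"protein {self.id!r} has an empty sequence")
        self.sequence = self.sequence.upper()
        if not self.mw:
            self.mw = protein_mw(self.sequence)
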