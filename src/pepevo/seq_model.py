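"""Peptide sequence model: alphabet, random initialisation, mutation, solubility.

The peptide being evolved is a plain string over the 20 canonical amino
acids plus a topology flag (linear or head-to-tail cyclic).  Initial
sequences are drawn by Gumbel-argmax over uniform logits — the argmax of
i.i.d. standard-Gumbel noise over equal weights is exactly uniform over the
alphabet — and the search proposes single-residue substitutions.

Solubility is judged from composition: charged residues (D, K, R, H, E)
must exceed 25% and hydrophobic residues (W, L, I, F, M, V, Y) must stay
below 25%, together with a mean peptide plDDT above 90.  All three
comparisons are strict.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import TYPE_CHECKING

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .losses import DesignRecord

CANONICAL_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"
CHARGED_RESIDUES = frozenset("DKRHE")
HYDROPHOBIC_RESIDUES = frozenset("WLIFMVY")

PLDDT_SOLUBILITY_MIN = 90.0
CHARGED_FRACTION_MIN = 0.25
HYDROPHOBIC_FRACTION_MAX = 0.25


class Topology(str, Enum):
    LINEAR = "linear"
    CYCLIC = "cyclic"


@dataclass(frozen=True)
class AminoAcidAlphabet:
    """Ordered residue alphabet with charged/hydrophobic subsets.

    The default is the 20 canonical one-letter codes; tests may use reduced
    sub-alphabets (the charged/hydrophobic subsets are intersected down).
    """

    residues: str = CANONICAL_RESIDUES
    charged: frozenset = field(default=CHARGED_RESIDUES)
    hydrophobic: frozenset = field(default=HYDROPHOBIC_RESIDUES)

    def __post_init__(self) -> None:
        if len(set(self.residues)) != len(self.residues):
            raise ValueError("alphabet residues must be unique")
        object.__setattr__(self, "charged", frozenset(self.charged) & set(self.residues))
        object.__setattr__(
            self, "hydrophobic", frozenset(self.hydrophobic) & set(self.residues)
        )
        if self.charged & self.hydrophobic:
            raise ValueError("charged and hydrophobic sets must be disjoint")

    def __len__(self) -> int:
        return len(self.residues)

    def index(self, residue: str) -> int:
        i = self.residues.find(residue)
        if i < 0:
            raise ValueError(f"residue {residue!r} not in alphabet")
        return i


DEFAULT_ALPHABET = AminoAcidAlphabet()


@dataclass(frozen=True)
class PeptideSequence:
    """A peptide: residue string + topology. Topology survives mutation."""

    residues: str
    topology: Topology = Topology.LINEAR
    alphabet: AminoAcidAlphabet = DEFAULT_ALPHABET

    def __post_init__(self) -> None:
        if len(self.residues) < 1:
            raise ValueError("peptide must have at least one residue")
        bad = set(self.residues) - set(self.alphabet.residues)
        if bad:
            raise ValueError(f"residues {sorted(bad)} not in alphabet")

    def __len__(self) -> int:
        return len(self.residues)

    def __str__(self) -> str:
        return self.residues


def gumbel_initialise(
    length: int,
    topology: Topology = Topology.LINEAR,
    seed: int = 0,
    alphabet: AminoAcidAlphabet = DEFAULT_ALPHABET,
) -> PeptideSequence:
    """Draw a random peptide by per-position Gumbel-argmax over the alphabet.

    For each of ``length`` positions an independent vector of standard
    Gumbel(0, 1) values (one per alphabet letter) is drawn and the argmax
    selects the residue.  Over equal logits this is exactly a uniform draw
    per position; identical ``(length, topology, seed)`` give identical
    sequences.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    rng = np.random.default_rng(seed)
    noise = rng.gumbel(loc=0.0, scale=1.0, size=(length, len(alphabet)))
    picks = noise.argmax(axis=1)
    residues = "".join(alphabet.residues[i] for i in picks)
    return PeptideSequence(residues, topology=topology, alphabet=alphabet)


def propose_mutation(seq: PeptideSequence, rng: np.random.Generator) -> PeptideSequence:
    """Substitute one residue: uniform position, uniform over the other letters.

    The returned sequence is always at Hamming distance exactly 1 from the
    input (the current residue is excluded from the draw) and keeps the
    input's topology and alphabet.
    """
    pos = int(rng.integers(len(seq)))
    current = seq.residues[pos]
    alternatives = [r for r in seq.alphabet.residues if r != current]
    if not alternatives:
        raise ValueError("alphabet too small to mutate")
    new = alternatives[int(rng.integers(len(alternatives)))]
    mutated = seq.residues[:pos] + new + seq.residues[pos + 1 :]
    return PeptideSequence(mutated, topology=seq.topology, alphabet=seq.alphabet)


def charged_fraction(seq: PeptideSequence | str) -> float:
    """Fraction of residues in {D, K, R, H, E}."""
    s = str(seq)
    return sum(r in CHARGED_RESIDUES for r in s) / len(s)


def hydrophobic_fraction(seq: PeptideSequence | str) -> float:
    """Fraction of residues in {W, L, I, F, M, V, Y}."""
    s = str(seq)
    return sum(r in HYDROPHOBIC_RESIDUES for r in s) / len(s)


def solubility_filter(record: "DesignRecord") -> bool:
    """True iff plDDT > 90 AND charged > 25% AND hydrophobic < 25% (all strict)."""
    plddt = record.peptide_plddt_design
    if plddt is None:
        raise ValueError("record has no design plDDT; cannot apply solubility filter")
    seq = str(record.sequence)
    return (
        plddt > PLDDT_SOLUBILITY_MIN
        and charged_fraction(seq) > CHARGED_FRACTION_MIN
        and hydrophobic_fraction(seq) < HYDROPHOBIC_FRACTION_MAX
    )
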