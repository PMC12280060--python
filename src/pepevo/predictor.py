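"""Structure-predictor contract, positional offsets, and toy surrogates.

Real design/validation networks (AlphaFold2-style for design, a
multimer-style network for cross-validation) are out of scope; what lives
here is (1) the relative positional offset matrices that encode linear vs
head-to-tail cyclic peptides for such networks, and (2) two deterministic
toy surrogate predictors — a "design" surrogate and an independent
"validation" surrogate — that satisfy the same contract and make the full
evolution/validation pipeline testable at desk scale.

Each surrogate hides a motif: the fraction of peptide positions matching
it sets a compatibility score s in [0, 1], which controls both placement
(distance to the receptor interpolates from d_far at s=0 to d_near at s=1)
and confidence (plDDT = 50 + 50·s).  Giving the two surrogates different
motifs manufactures adversarial sequences — confident and close under the
design surrogate, far away under validation, hence large ΔCOM — while
sequences matching both motifs are placed consistently (small ΔCOM).

Adapter configuration for real networks (executable, recycles, seeds,
early stopping) is declared in config files and documented in the methods
note; the MSA (A3M text) is passed through opaquely and never parsed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Protocol

import numpy as np

from .seq_model import PeptideSequence, Topology, gumbel_initialise
from .structgeom import PredictedComplex, Structure3D

CA_SPACING = 3.8  # Å, consecutive CA-CA distance in the toy traces
INTER_CHAIN_OFFSET = 200  # standard "separate chain" relative-position jump

AA3 = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE",
    "G": "GLY", "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU",
    "M": "MET", "N": "ASN", "P": "PRO", "Q": "GLN", "R": "ARG",
    "S": "SER", "T": "THR", "V": "VAL", "W": "TRP", "Y": "TYR",
}


def linear_offset(length: int) -> np.ndarray:
    """Default relative positional encoding: entry(i, j) = j - i."""
    if length < 1:
        raise ValueError("length must be >= 1")
    idx = np.arange(length)
    return idx[None, :] - idx[:, None]


def cyclic_offset(length: int) -> np.ndarray:
    """Signed circular separations, so first and last residues are adjacent.

    entry(i, j) is (j - i) mod L mapped into (-L/2, L/2]; for even L the
    antipodal tie is assigned +L/2.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    d = np.mod(linear_offset(length), length)
    d[d > length // 2] -= length
    if length % 2 == 0:
        d[d == -length // 2] = length // 2
    return d


@dataclass
class ReceptorInput:
    """Target receptor: sequence, 3D structure, optional opaque MSA text."""

    sequence: str
    structure: Structure3D
    msa: Optional[str] = None

    def __post_init__(self) -> None:
        if self.structure is not None and len(self.sequence) != self.structure.n_residues:
            raise ValueError("receptor sequence length must match structure residue count")


class Predictor(Protocol):
    """Contract every structure predictor satisfies.

    Pure: identical (receptor, sequence, offset, seed) give identical
    complexes, with finite coordinates and plDDT in [0, 100].
    """

    def __call__(
        self,
        receptor: ReceptorInput,
        seq: PeptideSequence,
        offset: np.ndarray,
        seed: int = 0,
    ) -> PredictedComplex: ...


def motif_for_length(length: int, motif_seed: int) -> str:
    """Deterministic hidden motif of a given length from a motif seed."""
    return gumbel_initialise(length, seed=(motif_seed * 1_000_003 + length) % 2**31).residues


@dataclass(frozen=True)
class ToySurrogate:
    """Deterministic toy predictor with a hidden motif.

    ``motif`` is either a fixed string (its length must then match every
    query) or None, in which case a per-length motif is derived from
    ``motif_seed``.  ``approach`` is the unit direction from the receptor
    towards the peptide; ``lateral`` shifts the placement axis so two
    surrogates can disagree geometrically.
    """

    motif: Optional[str] = None
    motif_seed: int = 0
    d_far: float = 25.0
    d_near: float = 3.0
    lateral_shift: float = 0.0
    emit_pae: bool = True

    def motif_for(self, length: int) -> str:
        if self.motif is not None:
            if len(self.motif) != length:
                raise ValueError(
                    f"configured motif length {len(self.motif)} != peptide length {length}"
                )
            return self.motif
        return motif_for_length(length, self.motif_seed)

    def score(self, seq: PeptideSequence) -> float:
        motif = self.motif_for(len(seq))
        return sum(a == b for a, b in zip(seq.residues, motif)) / len(seq)

    def __call__(
        self,
        receptor: ReceptorInput,
        seq: PeptideSequence,
        offset: np.ndarray,
        seed: int = 0,
    ) -> PredictedComplex:
        if receptor.structure is None:
            raise ValueError("toy surrogate requires a receptor structure")
        L = len(seq)
        if offset.shape != (L, L):
            raise ValueError("offset matrix side must equal peptide length")
        s = self.score(seq)
        height = self.d_far * (1.0 - s) + self.d_near * s
        cyclic = L >= 3 and np.array_equal(offset, cyclic_offset(L))
        peptide = self._place_peptide(receptor.structure, seq, height, cyclic)
        plddt = np.full(L, 50.0 + 50.0 * s)
        pae = self._pae(receptor.structure.n_residues, L, s) if self.emit_pae else None
        return PredictedComplex(receptor.structure, peptide, plddt, pae=pae)

    def _place_peptide(
        self, receptor: Structure3D, seq: PeptideSequence, height: float, cyclic: bool
    ) -> Structure3D:
        L = len(seq)
        anchor = receptor.ca_coords().mean(axis=0)
        top = receptor.coords[:, 2].max()
        base = np.array([anchor[0], anchor[1] + self.lateral_shift, top + height])
        if cyclic:
            radius = L * CA_SPACING / (2.0 * np.pi)
            theta = 2.0 * np.pi * np.arange(L) / L
            ca = base + np.stack(
                [radius * np.cos(theta), radius * np.sin(theta), np.zeros(L)], axis=1
            )
        else:
            xs = (np.arange(L) - (L - 1) / 2.0) * CA_SPACING
            ca = base + np.stack([xs, np.zeros(L), np.zeros(L)], axis=1)
        # CB sits 1.5 Å above CA, away from the receptor
        cb = ca + np.array([0.0, 0.0, 1.5])
        chain, resid, resname, atomname, coords = [], [], [], [], []
        for i, aa in enumerate(seq.residues):
            chain += ["B", "B"]
            resid += [i + 1, i + 1]
            resname += [AA3[aa], AA3[aa]]
            atomname += ["CA", "CB"]
            coords += [ca[i], cb[i]]
        return Structure3D(chain, resid, resname, atomname, np.asarray(coords))

    def _pae(self, n_rec: int, n_pep: int, s: float) -> np.ndarray:
        n = n_rec + n_pep
        inter = 2.0 + 18.0 * (1.0 - s)
        pae = np.full((n, n), 2.0)
        pae[:n_rec, n_rec:] = inter
        pae[n_rec:, :n_rec] = inter
        np.fill_diagonal(pae, 0.0)
        return pae


def toy_design_predictor(
    motif: Optional[str] = None, motif_seed: int = 11, **kw
) -> ToySurrogate:
    """The surrogate standing in for the design network."""
    return ToySurrogate(motif=motif, motif_seed=motif_seed, d_far=25.0, d_near=3.0, **kw)


def toy_validation_predictor(
    motif: Optional[str] = None, motif_seed: int = 23, **kw
) -> ToySurrogate:
    """The independently "trained" validation surrogate.

    Its default hidden motif differs from the design surrogate's and its
    far placement is 30 Å out, so a sequence matching only the design
    motif lands ~27 Å from the design placement (loss2 >> 1), while a
    sequence matching both motifs is placed consistently (ΔCOM ≈ 0).
    """
    kw.setdefault("d_far", 30.0)
    return ToySurrogate(motif=motif, motif_seed=motif_seed, d_near=3.0, **kw)


_REGISTRY: dict = {
    "toy-design": toy_design_predictor,
    "toy-validation": toy_validation_predictor,
}


def get_predictor(name: str, **kw) -> Predictor:
    """Resolve a predictor by registry name ("toy-design" / "toy-validation")."""
    try:
        factory: Callable = _REGISTRY[name]
    except KeyError:
        raise ValueError(f"unknown predictor {name!r}; known: {sorted(_REGISTRY)}")
    return factory(**kw)


def offset_for(seq: PeptideSequence) -> np.ndarray:
    """The offset matrix matching a peptide's topology."""
    if seq.topology is Topology.CYCLIC:
        return cyclic_offset(len(seq))
    return linear_offset(len(seq))
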