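"""3D structure containers and interface geometry.

Everything the design and validation losses consume lives here: per-atom
minimum distances between chains, receptor "target atoms" (the Cβ atoms
within 8 Å of the peptide, frozen from the design prediction), Cβ contact
maps, CA centres of mass and the ΔCOM between two peptide placements, and
interface-averaged PAE.

Conventions (documented once, enforced by the validators below):
coordinates in Å, 1-based residue numbering, chain A = receptor and
chain B = peptide, glycine's missing Cβ proxied by its CA, and all cutoff
comparisons strict ``<``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

CONTACT_CUTOFF = 8.0  # Å, Cβ–Cβ, strict "<"


@dataclass
class Structure3D:
    """A single-chain (or merged) set of heavy atoms.

    Parallel arrays over atoms: chain id, 1-based residue index, residue
    name (3-letter), atom name, and Nx3 coordinates in Å.
    """

    chain: np.ndarray
    resid: np.ndarray
    resname: np.ndarray
    atomname: np.ndarray
    coords: np.ndarray

    def __post_init__(self) -> None:
        self.chain = np.asarray(self.chain, dtype=object)
        self.resid = np.asarray(self.resid, dtype=int)
        self.resname = np.asarray(self.resname, dtype=object)
        self.atomname = np.asarray(self.atomname, dtype=object)
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be an (N, 3) array")
        if len(self.coords) == 0:
            raise ValueError("structure must contain at least one atom")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")

    def __len__(self) -> int:
        return len(self.coords)

    @property
    def residue_ids(self) -> np.ndarray:
        """Unique residue indices in order of first appearance."""
        _, first = np.unique(self.resid, return_index=True)
        return self.resid[np.sort(first)]

    @property
    def n_residues(self) -> int:
        return len(np.unique(self.resid))

    def atom_mask(self, name: str) -> np.ndarray:
        return self.atomname == name

    def ca_coords(self) -> np.ndarray:
        ca = self.coords[self.atom_mask("CA")]
        if len(ca) == 0:
            raise ValueError("structure has no CA atoms")
        return ca

    def cb_coords(self) -> tuple[np.ndarray, np.ndarray]:
        """One Cβ coordinate per residue (glycine falls back to CA).

        Returns (residue ids, coordinates), ordered by residue index.
        """
        ids, xyz = [], []
        for rid in sorted(np.unique(self.resid)):
            m = self.resid == rid
            names = self.atomname[m]
            crd = self.coords[m]
            if "CB" in names:
                xyz.append(crd[list(names).index("CB")])
            elif "CA" in names:
                xyz.append(crd[list(names).index("CA")])
            else:
                raise ValueError(f"residue {rid} has neither CB nor CA")
            ids.append(rid)
        return np.asarray(ids, dtype=int), np.asarray(xyz, dtype=float)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Structure3D":
        return Structure3D(
            self.chain.copy(),
            self.resid.copy(),
            self.resname.copy(),
            self.atomname.copy(),
            self.coords @ np.asarray(rotation).T + np.asarray(translation),
        )


@dataclass
class PredictedComplex:
    """Receptor + peptide prediction with per-residue confidence.

    ``peptide_plddt`` holds one value per peptide residue on the 0–100
    scale; ``pae`` (optional) is the square predicted-aligned-error matrix
    over receptor-then-peptide residues, in Å.
    """

    receptor: Structure3D
    peptide: Structure3D
    peptide_plddt: np.ndarray
    pae: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.peptide_plddt = np.asarray(self.peptide_plddt, dtype=float)
        if len(self.peptide_plddt) != self.peptide.n_residues:
            raise ValueError("peptide_plddt length must equal peptide residue count")
        if np.any(self.peptide_plddt < 0) or np.any(self.peptide_plddt > 100):
            raise ValueError("plDDT values must lie in [0, 100]")
        if self.pae is not None:
            self.pae = np.asarray(self.pae, dtype=float)
            n = self.receptor.n_residues + self.peptide.n_residues
            if self.pae.shape != (n, n):
                raise ValueError(f"PAE must be {n}x{n} over all residues")
            if np.any(self.pae < 0):
                raise ValueError("PAE must be non-negative")

    @property
    def mean_peptide_plddt(self) -> float:
        return float(self.peptide_plddt.mean())


@dataclass(frozen=True)
class ContactSet:
    """Inter-chain residue contacts: (receptor residue, peptide residue) pairs."""

    pairs: frozenset

    @property
    def receptor_residues(self) -> frozenset:
        return frozenset(r for r, _ in self.pairs)

    @property
    def peptide_residues(self) -> frozenset:
        return frozenset(p for _, p in self.pairs)

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass(frozen=True)
class TargetAtoms:
    """Receptor Cβ target atoms frozen from the design prediction.

    The *identity* (residue indices) is frozen; coordinates are re-resolved
    on whichever prediction is being scored, so a validation prediction
    with a differently placed receptor is measured against its own copy of
    the same residues.
    """

    residue_ids: tuple
    coords: np.ndarray = field(compare=False)

    def __len__(self) -> int:
        return len(self.residue_ids)

    def resolve(self, receptor: Structure3D) -> np.ndarray:
        """Cβ coordinates of the frozen residues on ``receptor``."""
        ids, xyz = receptor.cb_coords()
        lookup = {int(r): c for r, c in zip(ids, xyz)}
        try:
            return np.asarray([lookup[int(r)] for r in self.residue_ids])
        except KeyError as e:  # pragma: no cover - misuse guard
            raise ValueError(f"target residue {e} absent from receptor") from e


def min_distances_peptide_to_receptor(
    cx: PredictedComplex, receptor_subset: np.ndarray | None = None
) -> np.ndarray:
    """dj: for each peptide atom, distance to the nearest receptor atom.

    ``receptor_subset`` (an Mx3 coordinate array) restricts the receptor
    side, e.g. to the frozen target atoms.
    """
    if receptor_subset is None:
        rec = cx.receptor.coords
    else:
        rec = np.asarray(receptor_subset, dtype=float)
        if len(rec) == 0:
            raise ValueError("receptor_subset must be non-empty")
    return cdist(cx.peptide.coords, rec).min(axis=1)


def min_distances_target_to_peptide(
    target_coords: np.ndarray, peptide: Structure3D
) -> np.ndarray:
    """di: for each target atom, distance to the nearest peptide atom."""
    target_coords = np.asarray(target_coords, dtype=float)
    if len(target_coords) == 0:
        raise ValueError("target atom set must be non-empty")
    return cdist(target_coords, peptide.coords).min(axis=1)


def receptor_target_atoms(
    design: PredictedComplex, cutoff: float = CONTACT_CUTOFF
) -> TargetAtoms:
    """Receptor Cβs within ``cutoff`` Å of any peptide Cβ on the design prediction.

    May be empty (no interface); callers treat that as a flagged
    no-interface case rather than an error.
    """
    rec_ids, rec_cb = design.receptor.cb_coords()
    _, pep_cb = design.peptide.cb_coords()
    close = (cdist(rec_cb, pep_cb) < cutoff).any(axis=1)
    return TargetAtoms(tuple(int(r) for r in rec_ids[close]), rec_cb[close])


def ca_center_of_mass(peptide: Structure3D) -> np.ndarray:
    """Unweighted mean of the CA coordinates, Å."""
    return peptide.ca_coords().mean(axis=0)


def delta_com(peptide_design: Structure3D, peptide_validation: Structure3D) -> float:
    """ΔCOM: distance between the two peptides' CA centres of mass, Å."""
    return float(
        np.linalg.norm(ca_center_of_mass(peptide_design) - ca_center_of_mass(peptide_validation))
    )


def cb_contacts(cx: PredictedComplex, cutoff: float = CONTACT_CUTOFF) -> ContactSet:
    """All (receptor residue, peptide residue) pairs with Cβ–Cβ distance < cutoff."""
    rec_ids, rec_cb = cx.receptor.cb_coords()
    pep_ids, pep_cb = cx.peptide.cb_coords()
    d = cdist(rec_cb, pep_cb)
    ri, pi = np.nonzero(d < cutoff)
    return ContactSet(frozenset((int(rec_ids[i]), int(pep_ids[j])) for i, j in zip(ri, pi)))


def contact_similarity(design: ContactSet, wt: ContactSet) -> tuple[int, int, float]:
    """Compare a design's receptor contacts with the known binder's.

    Returns ``(n_design_contacts, n_matching_receptor_residues,
    fraction_of_wt)`` where the fraction is the design contact count over
    the WT contact count and the match count is the overlap of receptor
    residues touched by the two binders.
    """
    if len(wt) == 0:
        raise ValueError("WT contact set must be non-empty")
    n_design = len(design.pairs)
    n_matching = len(design.receptor_residues & wt.receptor_residues)
    return n_design, n_matching, n_design / len(wt.pairs)


def interface_pae_mean(
    cx: PredictedComplex, contact_cutoff: float = CONTACT_CUTOFF
) -> tuple[float, bool]:
    """Mean PAE over inter-chain residue pairs at the interface.

    Averages both off-diagonal blocks (PAE is asymmetric) restricted to
    Cβ-contact pairs; when there are no contacts, falls back to all
    inter-chain pairs and flags it.  Returns ``(mean, used_fallback)``.
    """
    if cx.pae is None:
        raise ValueError("complex has no PAE matrix")
    n_rec = cx.receptor.n_residues
    rec_ids = sorted(int(r) for r in np.unique(cx.receptor.resid))
    pep_ids = sorted(int(r) for r in np.unique(cx.peptide.resid))
    rec_pos = {r: i for i, r in enumerate(rec_ids)}
    pep_pos = {p: n_rec + i for i, p in enumerate(pep_ids)}

    contacts = cb_contacts(cx, cutoff=contact_cutoff)
    fallback = len(contacts) == 0
    if fallback:
        pairs = [(r, p) for r in rec_ids for p in pep_ids]
    else:
        pairs = sorted(contacts.pairs)
    vals = []
    for r, p in pairs:
        i, j = rec_pos[r], pep_pos[p]
        vals.append(cx.pae[i, j])
        vals.append(cx.pae[j, i])
    return float(np.mean(vals)), fallback
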