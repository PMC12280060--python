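"""File formats: PDB complexes (via gemmi), FASTA, PAE sidecars, record CSVs.

Conventions: chain A is the receptor, chain B the peptide; per-residue
plDDT is carried in the B-factor column of chain B (the convention used
by structure predictors); PAE travels in a JSON sidecar next to the PDB,
keyed ``"pae"`` as a row-major matrix; hydrogens are dropped on read.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Iterable, Optional, Sequence

import gemmi
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .losses import DesignRecord
from .seq_model import PeptideSequence, Topology
from .structgeom import PredictedComplex, Structure3D

_ELEMENT = {"CA": "C", "CB": "C", "N": "N", "C": "C", "O": "O", "S": "S"}


def _to_gemmi_chain(struct: Structure3D, chain_id: str, bfactors: Optional[dict] = None):
    chain = gemmi.Chain(chain_id)
    order = []
    seen = set()
    for rid in struct.resid:
        if rid not in seen:
            seen.add(rid)
            order.append(int(rid))
    for rid in order:
        mask = struct.resid == rid
        res = gemmi.Residue()
        res.name = str(struct.resname[mask][0])
        res.seqid = gemmi.SeqId(int(rid), " ")
        b = 0.0 if bfactors is None else float(bfactors.get(int(rid), 0.0))
        for name, xyz in zip(struct.atomname[mask], struct.coords[mask]):
            atom = gemmi.Atom()
            atom.name = str(name)
            atom.pos = gemmi.Position(*map(float, xyz))
            atom.element = gemmi.Element(_ELEMENT.get(str(name), str(name)[0]))
            atom.b_iso = b
            atom.occ = 1.0
            res.add_atom(atom)
        chain.add_residue(res)
    return chain


def write_complex(cx: PredictedComplex, path) -> None:
    """Write receptor (chain A) + peptide (chain B) to PDB; plDDT into B column."""
    st = gemmi.Structure()
    st.name = Path(str(path)).stem
    model = gemmi.Model(1)
    model.add_chain(_to_gemmi_chain(cx.receptor, "A"))
    pep_ids = sorted(int(r) for r in np.unique(cx.peptide.resid))
    bf = {rid: float(v) for rid, v in zip(pep_ids, cx.peptide_plddt)}
    model.add_chain(_to_gemmi_chain(cx.peptide, "B", bfactors=bf))
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))
    if cx.pae is not None:
        pae_sidecar(path).write_text(json.dumps({"pae": cx.pae.tolist()}))


def write_structure(struct: Structure3D, path, chain_id: str = "A") -> None:
    st = gemmi.Structure()
    st.name = Path(str(path)).stem
    model = gemmi.Model(1)
    model.add_chain(_to_gemmi_chain(struct, chain_id))
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))


def pae_sidecar(pdb_path) -> Path:
    return Path(str(pdb_path)).with_suffix(".pae.json")


def _chain_to_structure(chain) -> Structure3D:
    chains, resids, resnames, atomnames, coords = [], [], [], [], []
    for res in chain:
        for atom in res:
            if atom.element.is_hydrogen:
                continue
            chains.append(chain.name)
            resids.append(res.seqid.num)
            resnames.append(res.name)
            atomnames.append(atom.name)
            coords.append([atom.pos.x, atom.pos.y, atom.pos.z])
    if not coords:
        raise ValueError(f"chain {chain.name} has no heavy atoms")
    return Structure3D(chains, resids, resnames, atomnames, np.asarray(coords))


def read_structure(path, as_complex: bool = False):
    """Read a PDB file into a Structure3D, or a PredictedComplex when flagged.

    Complex mode expects chain A (receptor) and chain B (peptide), takes
    the peptide per-residue plDDT from chain B's B-factor column, and
    loads a PAE matrix from the ``.pae.json`` sidecar when present.
    """
    path = Path(str(path))
    if not path.exists():
        raise FileNotFoundError(path)
    st = gemmi.read_structure(str(path))
    st.remove_hydrogens()
    if len(st) == 0 or all(len(ch) == 0 for ch in st[0]):
        raise ValueError(f"{path}: no ATOM records")
    model = st[0]
    if not as_complex:
        merged = [_chain_to_structure(ch) for ch in model if len(ch) > 0]
        if len(merged) == 1:
            return merged[0]
        return Structure3D(
            np.concatenate([m.chain for m in merged]),
            np.concatenate([m.resid for m in merged]),
            np.concatenate([m.resname for m in merged]),
            np.concatenate([m.atomname for m in merged]),
            np.vstack([m.coords for m in merged]),
        )
    chains = {ch.name: ch for ch in model if len(ch) > 0}
    if "A" not in chains or "B" not in chains:
        raise ValueError(f"{path}: complex mode needs chains A (receptor) and B (peptide)")
    receptor = _chain_to_structure(chains["A"])
    peptide = _chain_to_structure(chains["B"])
    plddt = [float(res[0].b_iso) for res in chains["B"]]
    pae = None
    sidecar = pae_sidecar(path)
    if sidecar.exists():
        pae = np.asarray(json.loads(sidecar.read_text())["pae"], dtype=float)
    return PredictedComplex(receptor, peptide, np.asarray(plddt), pae=pae)


# --- FASTA -----------------------------------------------------------------

def write_fasta(records: Iterable[tuple], path) -> None:
    """Write (name, PeptideSequence) pairs; topology goes in the header."""
    out = []
    for name, seq in records:
        out.append(
            SeqRecord(Seq(seq.residues), id=name, description=f"topology={seq.topology.value}")
        )
    SeqIO.write(out, str(path), "fasta")


def read_fasta(path) -> list:
    """Read FASTA into (name, PeptideSequence) pairs; topology=... token honoured."""
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        topology = Topology.LINEAR
        for token in rec.description.split():
            if token.startswith("topology="):
                topology = Topology(token.split("=", 1)[1])
        out.append((rec.id, PeptideSequence(str(rec.seq), topology=topology)))
    return out


def read_receptor_fasta(path) -> str:
    recs = list(SeqIO.parse(str(path), "fasta"))
    if not recs:
        raise ValueError(f"{path}: no FASTA records")
    return str(recs[0].seq)


# --- record CSVs -----------------------------------------------------------

RECORD_COLUMNS = [
    "length", "topology", "restart", "iteration", "sequence",
    "loss1", "loss2", "combined", "plddt_design", "plddt_validation",
    "delta_com", "charged", "hydrophobic", "n_contacts", "no_interface",
    "is_top", "is_adversarial", "is_final",
]


def records_to_frame(
    records: Sequence[DesignRecord],
    top: set = frozenset(),
    adversarial: set = frozenset(),
    final: set = frozenset(),
) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append(
            {
                "length": len(r.sequence),
                "topology": r.sequence.topology.value,
                "restart": r.restart,
                "iteration": r.iteration,
                "sequence": r.sequence.residues,
                "loss1": r.loss1,
                "loss2": r.loss2,
                "combined": r.combined,
                "plddt_design": r.peptide_plddt_design,
                "plddt_validation": r.peptide_plddt_validation,
                "delta_com": r.delta_com,
                "charged": r.charged,
                "hydrophobic": r.hydrophobic,
                "n_contacts": r.n_contacts,
                "no_interface": r.no_interface,
                "is_top": id(r) in top,
                "is_adversarial": id(r) in adversarial,
                "is_final": id(r) in final,
            }
        )
    return pd.DataFrame(rows, columns=RECORD_COLUMNS)


def frame_to_records(df: pd.DataFrame) -> list:
    """Rebuild DesignRecords (without stored complexes) from a record CSV frame."""
    out = []
    for _, row in df.iterrows():
        def _opt(v):
            return None if v is None or (isinstance(v, float) and math.isnan(v)) else float(v)

        out.append(
            DesignRecord(
                sequence=PeptideSequence(row["sequence"], topology=Topology(row["topology"])),
                iteration=int(row["iteration"]),
                restart=int(row["restart"]),
                loss1=float(row["loss1"]),
                loss2=_opt(row.get("loss2")),
                peptide_plddt_design=_opt(row.get("plddt_design")),
                peptide_plddt_validation=_opt(row.get("plddt_validation")),
                delta_com=_opt(row.get("delta_com")),
                no_interface=bool(row.get("no_interface", False)),
            )
        )
    return out
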