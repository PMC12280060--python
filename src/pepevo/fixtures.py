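"""Deterministic toy fixtures: receptor, WT reference complex, sensorgrams.

The toy receptor is a 20-residue strand along x (CA spacing 3.8 Å, Cβ
offset 1.5 Å in y) that serves as the docking surface for the toy
surrogate predictors.  The WT reference complex docks the known
11-residue binder PYVPVHFDASV onto it at full compatibility, giving a
Cβ-contact set whose size is recorded in the manifest so contact
similarity has a fixed denominator.  The example sensorgram is simulated
at ka = 1e5 M⁻¹s⁻¹, kd = 0.12 s⁻¹ (Kd = 1.2 μM, the affinity scale of a
moderate peptide binder) and Rmax = 20 RU.

Regenerating with the same seed reproduces byte-identical files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .pdbio import write_complex, write_fasta, write_structure
from .predictor import AA3, CA_SPACING, ReceptorInput, ToySurrogate, linear_offset
from .seq_model import PeptideSequence, Topology
from .spr_kinetics import InjectionSchedule, KineticParams, simulate_single_cycle
from .structgeom import Structure3D, cb_contacts

WT_BINDER = "PYVPVHFDASV"  # known positive-control binder, 11 residues
RECEPTOR_SEQUENCE = "ACDEFGHIKLMNPQRSTVWY"  # one of each canonical residue
FIXTURE_SPR_PARAMS = KineticParams(ka=1e5, kd=0.12, rmax=20.0)


def toy_receptor(sequence: str = RECEPTOR_SEQUENCE) -> Structure3D:
    """Extended strand receptor: CA at (i·3.8, 0, 0), Cβ 1.5 Å off in y."""
    chain, resid, resname, atomname, coords = [], [], [], [], []
    for i, aa in enumerate(sequence):
        x = i * CA_SPACING
        chain.append("A"); resid.append(i + 1); resname.append(AA3[aa])
        atomname.append("CA"); coords.append([x, 0.0, 0.0])
        if aa != "G":
            chain.append("A"); resid.append(i + 1); resname.append(AA3[aa])
            atomname.append("CB"); coords.append([x, 1.5, 0.0])
    return Structure3D(chain, resid, resname, atomname, np.asarray(coords))


def toy_receptor_input(sequence: str = RECEPTOR_SEQUENCE) -> ReceptorInput:
    return ReceptorInput(sequence, toy_receptor(sequence))


def wt_reference_complex():
    """The WT binder docked at full compatibility: the contact benchmark."""
    receptor = toy_receptor_input()
    surrogate = ToySurrogate(motif=WT_BINDER)
    seq = PeptideSequence(WT_BINDER, topology=Topology.LINEAR)
    return surrogate(receptor, seq, linear_offset(len(seq)))


@dataclass
class FixtureSet:
    root: Path
    receptor_pdb: Path
    receptor_fasta: Path
    wt_complex_pdb: Path
    motifs_json: Path
    sensorgram_csv: Path
    manifest_json: Path


def make_fixtures(output_dir, seed: int = 0) -> FixtureSet:
    """Write the deterministic fixture set; same seed → byte-identical files."""
    root = Path(str(output_dir))
    root.mkdir(parents=True, exist_ok=True)

    receptor = toy_receptor_input()
    receptor_pdb = root / "receptor.pdb"
    write_structure(receptor.structure, receptor_pdb)
    receptor_fasta = root / "receptor.fasta"
    write_fasta(
        [("toy-receptor", PeptideSequence(receptor.sequence))], receptor_fasta
    )

    wt = wt_reference_complex()
    wt_pdb = root / "wt_complex.pdb"
    write_complex(wt, wt_pdb)
    wt_contacts = cb_contacts(wt)

    motifs = {
        "design": {"motif_seed": 11, "note": "per-length motifs derive from the seed"},
        "validation": {"motif_seed": 23},
        "wt_binder": WT_BINDER,
    }
    motifs_json = root / "motifs.json"
    motifs_json.write_text(json.dumps(motifs, indent=1, sort_keys=True))

    gram = simulate_single_cycle(
        FIXTURE_SPR_PARAMS,
        InjectionSchedule.single_cycle_default(),
        noise_sd=0.4,
        seed=seed,
    )
    sensorgram_csv = root / "sensorgram.csv"
    gram.to_csv(sensorgram_csv)

    manifest = {
        "seed": seed,
        "receptor_sequence": RECEPTOR_SEQUENCE,
        "receptor_n_residues": receptor.structure.n_residues,
        "receptor_n_atoms": len(receptor.structure),
        "wt_binder": WT_BINDER,
        "wt_contact_count": len(wt_contacts),
        "spr": {
            "ka": FIXTURE_SPR_PARAMS.ka,
            "kd": FIXTURE_SPR_PARAMS.kd,
            "rmax": FIXTURE_SPR_PARAMS.rmax,
            "Kd_M": FIXTURE_SPR_PARAMS.Kd,
            "noise_sd_RU": 0.4,
        },
    }
    manifest_json = root / "manifest.json"
    manifest_json.write_text(json.dumps(manifest, indent=1, sort_keys=True))

    return FixtureSet(
        root, receptor_pdb, receptor_fasta, wt_pdb, motifs_json, sensorgram_csv, manifest_json
    )
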