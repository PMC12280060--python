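"""In-silico directed evolution of peptide binders.

The search is a seeded hill-climb: a random peptide is drawn by
Gumbel-argmax, and for a fixed number of iterations a single-residue
mutation of the current best sequence is proposed, scored with the design
loss on the design predictor, and accepted only on strict improvement.
The whole procedure is repeated from several random starting points
(restarts) and across a ladder of peptide lengths and topologies.

Survivors (the best record of each restart) are then cross-validated once
with the independent validation predictor, which fills in the adversarial
loss, and the campaign applies the two selection rules (best combined
loss per length; adversarial pick with loss2 > 1) and the composition
solubility filter.

All randomness derives from a single campaign seed via keyed seed
derivation, so any (length, topology, restart) cell is independently
reproducible.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .losses import DesignRecord, loss2, select_adversarial, select_top
from .predictor import Predictor, ReceptorInput, get_predictor, offset_for
from .seq_model import (
    DEFAULT_ALPHABET,
    AminoAcidAlphabet,
    Topology,
    gumbel_initialise,
    propose_mutation,
    solubility_filter,
)
from .structgeom import PredictedComplex, receptor_target_atoms
from . import losses as _losses

log = logging.getLogger("pepevo")


def derive_seed(campaign_seed: int, *keys) -> int:
    """Deterministic child seed from a campaign seed and a key tuple."""
    ints = [int(campaign_seed)]
    for k in keys:
        ints.append(int(k) if isinstance(k, (int, np.integer)) else abs(hash(str(k))) % 2**31)
    return int(np.random.SeedSequence(ints).generate_state(1)[0] % 2**31)


@dataclass
class EvolutionConfig:
    """Search hyperparameters for a design campaign."""

    iterations: int = 1000
    restarts: int = 5
    lengths: Sequence[int] = tuple(range(8, 21))
    topologies: Sequence[Topology] = (Topology.LINEAR,)
    seed: int = 0
    design_predictor: str = "toy-design"
    validation_predictor: str = "toy-validation"
    adversarial_threshold: float = 1.0
    alphabet: AminoAcidAlphabet = DEFAULT_ALPHABET
    design_predictor_kwargs: dict = field(default_factory=dict)
    validation_predictor_kwargs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.iterations < 0:
            raise ValueError("iterations must be >= 0")
        if self.restarts < 1:
            raise ValueError("restarts must be >= 1")
        if any(L < 1 for L in self.lengths):
            raise ValueError("all peptide lengths must be >= 1")
        self.topologies = tuple(Topology(t) for t in self.topologies)


@dataclass
class TrajectoryStep:
    iteration: int
    sequence: str
    loss1: float
    accepted: bool
    best_loss1: float
    failed: bool = False


@dataclass
class Trajectory:
    """Per-iteration history of one restart's hill-climb."""

    length: int
    topology: Topology
    restart: int
    steps: list = field(default_factory=list)

    def best_curve(self) -> np.ndarray:
        return np.asarray([s.best_loss1 for s in self.steps])

    def __len__(self) -> int:
        return len(self.steps)


def evolve(
    receptor: ReceptorInput,
    predictor: Predictor,
    length: int,
    topology: Topology = Topology.LINEAR,
    iterations: int = 1000,
    seed: int = 0,
    restart: int = 0,
    alphabet: AminoAcidAlphabet = DEFAULT_ALPHABET,
) -> tuple[Trajectory, DesignRecord]:
    """Run one restart of the accept-if-strictly-better search.

    Returns the full trajectory (iteration 0 is the initial sequence) and
    the best record, which carries the design prediction for later
    cross-validation.  A predictor failure marks the iteration failed and
    the proposal rejected; the run continues.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    init_seed = derive_seed(seed, "init")
    mut_rng = np.random.default_rng(derive_seed(seed, "mutate"))

    best_seq = gumbel_initialise(length, topology, init_seed, alphabet)
    best_cx = predictor(receptor, best_seq, offset_for(best_seq), seed=init_seed)
    best_loss = _losses.loss1(best_cx)
    traj = Trajectory(length, topology, restart)
    traj.steps.append(TrajectoryStep(0, best_seq.residues, best_loss, True, best_loss))
    best_iteration = 0

    for it in range(1, iterations + 1):
        proposal = propose_mutation(best_seq, mut_rng)
        try:
            cx = predictor(receptor, proposal, offset_for(proposal), seed=init_seed)
            val = _losses.loss1(cx)
        except Exception as exc:  # predictor failure: reject, keep going
            log.warning("iteration=%d failed error=%s", it, exc)
            traj.steps.append(
                TrajectoryStep(it, proposal.residues, math.nan, False, best_loss, failed=True)
            )
            continue
        accepted = val < best_loss
        if accepted:
            best_seq, best_cx, best_loss, best_iteration = proposal, cx, val, it
        traj.steps.append(TrajectoryStep(it, proposal.residues, val, accepted, best_loss))

    record = DesignRecord(
        sequence=best_seq,
        iteration=best_iteration,
        restart=restart,
        loss1=best_loss,
        peptide_plddt_design=best_cx.mean_peptide_plddt,
        design_complex=best_cx,
    )
    return traj, record


def validate_candidates(
    records: Sequence[DesignRecord],
    receptor: ReceptorInput,
    validator: Predictor,
) -> list[DesignRecord]:
    """Cross-validate candidates with the independent validation predictor.

    For each record the target atoms are frozen from its stored design
    prediction, the validation predictor is run once, and loss2, the
    combined loss, ΔCOM and the validation plDDT are filled in.  An empty
    design interface flags the record and sets loss2 to +inf.
    """
    out = []
    for rec in records:
        if rec.design_complex is None:
            raise ValueError("record has no stored design prediction")
        val_cx = validator(receptor, rec.sequence, offset_for(rec.sequence))
        targets = receptor_target_atoms(rec.design_complex)
        if len(targets) == 0:
            out.append(
                rec.with_validation(
                    loss2=math.inf,
                    no_interface=True,
                    peptide_plddt_validation=val_cx.mean_peptide_plddt,
                    validation_complex=val_cx,
                    n_contacts=0,
                )
            )
            continue
        l2 = loss2(rec.design_complex, val_cx, target_atoms=targets)
        from .structgeom import delta_com as _dcom

        out.append(
            rec.with_validation(
                loss2=l2,
                delta_com=_dcom(rec.design_complex.peptide, val_cx.peptide),
                peptide_plddt_validation=val_cx.mean_peptide_plddt,
                validation_complex=val_cx,
                n_contacts=len(targets),
            )
        )
    return out


@dataclass
class CampaignResult:
    """Everything a design campaign produced."""

    config: EvolutionConfig
    trajectories: list
    candidates: list  # validated best-of-restart records
    top: dict  # (topology, length) -> DesignRecord
    adversarial: dict  # (topology, length) -> DesignRecord
    finals: list  # top selections passing the solubility filter

    def to_frame(self) -> pd.DataFrame:
        """One row per evaluated candidate (every iteration of every restart)."""
        rows = []
        for traj in self.trajectories:
            for s in traj.steps:
                rows.append(
                    {
                        "length": traj.length,
                        "topology": traj.topology.value,
                        "restart": traj.restart,
                        "iteration": s.iteration,
                        "sequence": s.sequence,
                        "loss1": s.loss1,
                        "accepted": s.accepted,
                        "best_loss1": s.best_loss1,
                        "failed": s.failed,
                    }
                )
        return pd.DataFrame(rows)

    def candidates_frame(self) -> pd.DataFrame:
        from .pdbio import records_to_frame

        return records_to_frame(
            self.candidates,
            top=set(map(id, self.top.values())),
            adversarial=set(map(id, self.adversarial.values())),
            final=set(map(id, self.finals)),
        )


def run_campaign(receptor: ReceptorInput, config: EvolutionConfig) -> CampaignResult:
    """Full design campaign: evolve, cross-validate, select, filter."""
    design = get_predictor(config.design_predictor, **config.design_predictor_kwargs)
    validator = get_predictor(config.validation_predictor, **config.validation_predictor_kwargs)

    trajectories: list = []
    survivors: list = []
    for topology in config.topologies:
        for length in config.lengths:
            for restart in range(config.restarts):
                run_seed = derive_seed(config.seed, topology.value, length, restart)
                traj, rec = evolve(
                    receptor,
                    design,
                    length,
                    topology=topology,
                    iterations=config.iterations,
                    seed=run_seed,
                    restart=restart,
                    alphabet=config.alphabet,
                )
                log.info(
                    "cell topology=%s length=%d restart=%d seed=%d best_loss1=%.4g",
                    topology.value, length, restart, run_seed, rec.loss1,
                )
                trajectories.append(traj)
                survivors.append(rec)

    candidates = validate_candidates(survivors, receptor, validator)

    top: dict = {}
    adversarial: dict = {}
    for topology in config.topologies:
        group = [c for c in candidates if c.sequence.topology is topology]
        if not group:
            continue
        for length, rec in select_top(group).items():
            top[(topology, length)] = rec
        for length, rec in select_adversarial(group, config.adversarial_threshold).items():
            adversarial[(topology, length)] = rec

    finals = [rec for rec in top.values() if solubility_filter(rec)]
    return CampaignResult(config, trajectories, candidates, top, adversarial, finals)
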