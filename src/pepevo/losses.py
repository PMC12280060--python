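"""Design and adversarial validation losses, and candidate selection.

The design loss (loss 1) rewards confident predictions that place every
peptide atom close to the receptor::

    loss1 = (mean peptide plDDT)^-1 * mean_j d_j

with d_j the distance from peptide atom j to the nearest receptor atom
(full receptor) and plDDT on the 0–100 scale, so a confident 4 Å-contact
design scores around 4/90 ≈ 0.044.

The validation loss (loss 2) scores the *agreement* between the design
network's complex and an independently trained validation network's
complex for the same sequence::

    loss2 = (mean validation plDDT)^-1 * (mean_i d_i + mean_j d_j) * 1/2 * ΔCOM

where the target atoms (receptor Cβs within 8 Å of the peptide on the
design prediction) are frozen, d_i runs from each target atom to the
nearest peptide atom and d_j from each peptide atom to the nearest target
atom — both measured on the validation prediction — and ΔCOM is the CA
centre-of-mass distance between the two predicted peptides.  A sequence
the two networks place identically scores 0; a sequence that fools only
the design network scores large.  Candidates with loss2 > 1 are treated as
adversarial.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.stats import spearmanr

from .seq_model import PeptideSequence, charged_fraction, hydrophobic_fraction
from .structgeom import (
    PredictedComplex,
    TargetAtoms,
    delta_com,
    min_distances_peptide_to_receptor,
    min_distances_target_to_peptide,
    receptor_target_atoms,
)

PLDDT_EPS = 1e-6
ADVERSARIAL_LOSS2_THRESHOLD = 1.0


@dataclass
class DesignRecord:
    """One evaluated candidate: sequence, scores, and bookkeeping."""

    sequence: PeptideSequence
    iteration: int = 0
    restart: int = 0
    loss1: float = math.nan
    loss2: Optional[float] = None
    peptide_plddt_design: Optional[float] = None
    peptide_plddt_validation: Optional[float] = None
    delta_com: Optional[float] = None
    charged: float = field(default=math.nan)
    hydrophobic: float = field(default=math.nan)
    no_interface: bool = False
    n_contacts: Optional[int] = None
    design_complex: Optional[PredictedComplex] = field(default=None, repr=False)
    validation_complex: Optional[PredictedComplex] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if math.isnan(self.charged):
            self.charged = charged_fraction(self.sequence)
        if math.isnan(self.hydrophobic):
            self.hydrophobic = hydrophobic_fraction(self.sequence)

    @property
    def combined(self) -> Optional[float]:
        if self.loss2 is None or math.isnan(self.loss1):
            return None
        return self.loss1 + self.loss2

    def with_validation(self, **kw) -> "DesignRecord":
        return replace(self, **kw)


def loss1(cx: PredictedComplex) -> float:
    """Design loss: inverse mean peptide plDDT times mean peptide→receptor distance."""
    mean_plddt = cx.mean_peptide_plddt
    if mean_plddt <= PLDDT_EPS:
        raise ValueError("mean peptide plDDT is degenerate (<= 1e-6)")
    dj = min_distances_peptide_to_receptor(cx)
    return float(dj.mean() / mean_plddt)


def loss2(
    design: PredictedComplex,
    validation: PredictedComplex,
    target_atoms: TargetAtoms | None = None,
) -> float:
    """Adversarial validation loss between design and validation predictions.

    ``target_atoms`` defaults to the set frozen from the design prediction;
    an empty interface yields +inf (flagged by callers) so ranking degrades
    gracefully instead of erroring the campaign.
    """
    if target_atoms is None:
        target_atoms = receptor_target_atoms(design)
    if len(target_atoms) == 0:
        return math.inf
    mean_plddt = validation.mean_peptide_plddt
    if mean_plddt <= PLDDT_EPS:
        raise ValueError("mean validation plDDT is degenerate (<= 1e-6)")
    target_xyz = target_atoms.resolve(validation.receptor)
    di = min_distances_target_to_peptide(target_xyz, validation.peptide)
    dj = min_distances_peptide_to_receptor(validation, receptor_subset=target_xyz)
    dcom = delta_com(design.peptide, validation.peptide)
    return float((di.mean() + dj.mean()) * 0.5 * dcom / mean_plddt)


def combined_loss(record: DesignRecord) -> float:
    """Sum of the design and validation losses."""
    c = record.combined
    if c is None:
        raise ValueError("record is missing loss1 or loss2")
    return c


def _lengths(records: Iterable[DesignRecord]) -> dict:
    by_len: dict = {}
    for r in records:
        by_len.setdefault(len(r.sequence), []).append(r)
    return by_len


def select_top(records: Sequence[DesignRecord]) -> dict:
    """Best combined-loss record per peptide length.

    Ties break on lower loss1, then lower iteration index.
    """
    if not records:
        raise ValueError("no records to select from")
    out = {}
    for length, recs in _lengths(records).items():
        out[length] = min(recs, key=lambda r: (combined_loss(r), r.loss1, r.iteration))
    return out


def select_adversarial(
    records: Sequence[DesignRecord], threshold: float = ADVERSARIAL_LOSS2_THRESHOLD
) -> dict:
    """Per length: the lowest-loss1 record among those with loss2 strictly > threshold.

    Lengths where nothing crosses the threshold are absent from the result
    (absence is a valid outcome).  Records flagged no-interface carry
    loss2 = +inf as a ranking sentinel, not a measured disagreement, so
    they are excluded here: without a design interface there is nothing
    for the validation network to dispute.
    """
    out = {}
    for length, recs in _lengths(records).items():
        pool = [
            r
            for r in recs
            if r.loss2 is not None and math.isfinite(r.loss2) and r.loss2 > threshold
        ]
        if pool:
            out[length] = min(pool, key=lambda r: (r.loss1, r.iteration))
    return out


def spearman_report(metrics: dict, kd_values: Sequence[float]) -> dict:
    """Spearman rank correlation of each in-silico metric against measured Kd.

    ``metrics`` maps metric name -> sequence of values paired with
    ``kd_values``.  Average-rank tie handling (scipy's default).  Metrics
    with fewer than 3 pairs are flagged as insufficient rather than
    correlated.
    """
    kd = np.asarray(kd_values, dtype=float)
    report = {}
    for name, vals in metrics.items():
        v = np.asarray(vals, dtype=float)
        if len(v) != len(kd):
            raise ValueError(f"metric {name!r} length mismatch with Kd values")
        if len(v) < 3:
            report[name] = {"spearman_r": math.nan, "n": len(v), "insufficient": True}
            continue
        rho = spearmanr(v, kd).statistic
        report[name] = {"spearman_r": float(rho), "n": len(v), "insufficient": False}
    return report
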