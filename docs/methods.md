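# Methods

## Design objective

A candidate peptide is evaluated in complex with the receptor by a
structure predictor that returns coordinates and per-residue confidence
(plDDT, 0–100). The design loss multiplies inverse mean peptide plDDT by
the mean over peptide atoms of the distance to the nearest receptor atom
(heavy atoms only; hydrogens are dropped on file read). Both factors are
necessary: distance alone rewards collapsed or unconfident placements,
confidence alone rewards peptides folded far from the receptor. plDDT is
kept on the 0–100 scale, so a confident design hugging the receptor at
3–5 Å scores in the 0.03–0.06 range; converged toy runs land at 0.0375,
consistent with the 0.04–0.1 window in which selected designs typically
fall.

## Search

Sequences are initialised by drawing, per position, 20 i.i.d. standard
Gumbel(0, 1) values and taking the argmax. Over equal logits this is
exactly a uniform draw per position — the Gumbel-argmax construction is
used so that an adapter wired to real network logits reduces to the same
code path. Each iteration mutates one uniformly chosen position of the
current best sequence to one of the 19 other residues (a no-op mutation
would waste an iteration) and accepts only strict improvement; equal
loss rejects, preventing neutral drift. Defaults are 1000 iterations and
5 restarts per length, lengths 8–20. Every (length, topology, restart)
cell derives its own seed from the campaign seed through
`numpy.random.SeedSequence` keyed derivation, and initialisation and
mutation use separate derived streams, so any cell is reproducible in
isolation. A predictor failure marks the iteration failed and rejected;
the run continues.

## Cyclic topology

Head-to-tail cyclisation is encoded in the relative positional offset
matrix handed to the predictor: entry (i, j) is the signed shortest path
from i to j on an L-cycle, mapped into (−L/2, L/2], with the even-L
antipodal tie assigned +L/2 (a convention adapters must match). Linear
peptides use entry (i, j) = j − i. Offsets are produced for the peptide
chain only; receptor/inter-chain offsets follow the usual separate-chain
convention of a large fixed jump.

## Adversarial cross-validation

The validation loss freezes the *identity* (residue indices) of the
receptor target Cβs found within 8 Å of the peptide Cβs on the design
prediction, re-resolves their coordinates on the validation prediction,
and combines three terms: mean distance from each target atom to the
nearest peptide atom (coverage — short distances to only a few target
residues are not enough), mean distance from each peptide atom to the
nearest target atom, and the CA centre-of-mass displacement between the
two networks' peptides, divided by mean validation plDDT. The 8 Å
criterion is Cβ–Cβ with strict `<` (glycine's Cβ proxied by CA); a
Cβ–any-atom variant is available via the cutoff argument. A design with
no target atoms gets loss2 = +∞ as a ranking sentinel and a no-interface
flag rather than an error.

Selection takes the minimum loss1 + loss2 per length (ties: lower loss1,
then earlier iteration). The adversarial selection takes, per length,
the lowest-loss1 record among those with loss2 strictly greater than 1;
no-interface sentinels are excluded from it, since without a design
interface there is no disagreement to measure. Validation runs once per
surviving candidate after the search, not inside the loop; per-iteration
validation is possible by calling `validate_candidates` on trajectory
records, but final-only is the default. The solubility filter uses the
*design* plDDT (the validation value is recorded alongside) and all
three thresholds are strict inequalities.

## Toy surrogate predictors

The two surrogates stand in for the design and validation networks. Each
hides a motif (fixed string, or derived per length from a motif seed);
the fraction s of matching positions sets the placement height above a
20-residue strand receptor, d(s) = d_far·(1 − s) + d_near·s (design:
25 → 3 Å; validation: 30 → 3 Å), and the confidence, plDDT = 50 + 50·s.
Linear offsets produce an open CA/CB strand (3.8 Å spacing), cyclic
offsets a closed ring of the same arc length. Both surrogates share the
placement axis, so a sequence matching both motifs is placed consistently
(ΔCOM ≈ 0, loss2 ≈ 0) while a sequence matching only the design motif
sits 3 Å out under design and 30 Å out under validation (ΔCOM ≈ 27 Å,
loss2 ≫ 1) — true positives and adversarial cases exist by construction.
A PAE matrix is emitted with inter-chain error 2 + 18·(1 − s) Å so the
interface-PAE metric is exercised end to end.

What the surrogate landscape shares with the real one: a global optimum
at high confidence and tight contact, adversarial sequences, and empty
interfaces for poor designs. What it does not: ruggedness (loss1 is a
strictly monotone function of match count, so hill-climbing converges
far more reliably than against a neural landscape), receptor
flexibility, and any physics of binding. Passing recovery tests
demonstrates the machinery of the loop, not designability of real
targets.

## Interface metrics

Cβ contacts are residue pairs with Cβ–Cβ distance < 8 Å. Contact
similarity against the reference binder reports the design's contact
count, the overlap of receptor residues with the reference's, and the
contact-count fraction of the reference total (the 65-contact known
binder in the fixture benchmark). Interface PAE averages both
off-diagonal blocks (PAE is asymmetric) over contact pairs, falling back
to all inter-chain pairs — flagged — when no contacts exist.

## SPR kinetics

Single-cycle sensorgrams follow the 1:1 model dR/dt = ka·C·(Rmax − R)
− kd·R. Within a constant-concentration segment the closed form is
mono-exponential relaxation towards Req = ka·C·Rmax/(ka·C + kd) at rate
kobs = ka·C + kd; the response is carried continuously across segment
boundaries (no regeneration) and the final buffer segment decays as
exp(−kd·t). The closed form is exact — an LSODA integration of the rate
equation agrees to < 0.1 RU over the full default cycle (2 nM, 20 nM,
200 nM, 2 μM, 20 μM at 120 s each, then 1800 s dissociation, 1 s
sampling).

Fitting is global least squares over (log10 ka, log10 kd, Rmax) with
bounds ka ∈ [1e2, 1e9] M⁻¹s⁻¹, kd ∈ [1e-6, 1] s⁻¹, Rmax ∈ (0, 1e4] RU,
multi-started from 5 log-spaced ka guesses when no initial guess is
given; Rmax is shared across the cycle's injections (per-sample Rmax
across *different* sensorgrams is simply separate fits). Traces whose
response range is below 10× a robust noise-floor estimate (median
absolute first difference scaled to point noise) are flagged
non-identifiable instead of fitted. Mass transport, drift and bulk
refractive-index steps are not modelled: the fit expects
reference/blank-subtracted data. Noiseless recovery is exact to
numerical precision; at 0.4 RU noise (2% of a 20 RU Rmax) the median Kd
error over 20 seeds is well under 10%.

## Problem sizes and numerical choices

The test and acceptance workloads run the evolution studies at L = 4
over a reduced 4-letter alphabet (500 iterations, 20 seeds) and toy
campaigns at tens of iterations — sizes chosen so the whole suite
exercises every stage in seconds while the landscape argument above
makes larger sizes uninformative for the surrogate. Distances use exact
all-pairs minima (`scipy.spatial.distance.cdist`); a 1e-6 guard on mean
plDDT precedes inversion; PDB coordinates round-trip at the format's
1e-3 Å precision; file conventions are chain A = receptor, chain B =
peptide, 1-based residue numbering, plDDT in the B-factor column and PAE
in a `.pae.json` sidecar.

## Limitations

No neural predictors are bundled or invoked; adapters are configuration
only. MSAs (A3M) are passed through opaquely, never parsed. Non-canonical
amino acids, mmCIF, hetero atoms and solvent are out of scope. The SPR
module models only the subtracted 1:1 signal, not instrument artefacts.
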