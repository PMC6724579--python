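# Methods

This note documents the models, numerical choices and limitations behind
`structimm`, in the spirit of a methods appendix.

## Structural model

A `Complex` is a set of chains with one chain designated as the presented
peptide, normalized to positions p1..p9 on load regardless of author
numbering, because every downstream feature is indexed by peptide position.
Hydrogens are neither read nor generated: all terms are heavy-atom
parameterized, matching the information actually present in most crystal
structures. Alternate locations resolve to the highest-occupancy copy
(ties to first occurrence); HETATM records (waters, ions, ligands) are
dropped — how templates' solvent should be treated before modeling is
genuinely open, and dropping it is the simplest defensible policy.

Superposition is the closed-form Kabsch solution with the reflection
branch folded to a proper rotation; collinear or <3-point inputs raise a
degenerate-geometry error rather than returning an arbitrary frame. RMSDs
are reported in two frames. The default, `groove`, superposes on groove
Cα atoms and evaluates the peptide without refitting: it measures how the
peptide sits *within* the groove, which is the quantity of interest when
comparing a model against a reference complex. `peptide` fits on the
peptide itself and measures pure conformational difference. Sequence
mismatches pair backbone plus shared side-chain atom names.

## Energy function

The scorer is a pluggable backend over a registry of 18 complex-level
terms (weighted sum = total; lower is more favorable) and 9 atomic-level
per-residue terms — the per-residue set deliberately excludes terms
descriptive of particular amino acids (reference energies, rotamer priors,
planarity) so positional features describe physics, not identity. The
built-in desk backend uses standard functional forms:

- **fa_atr / fa_rep** — 12-6 Lennard-Jones split at the minimum
  (r_min = sum of vdW radii, ε = geometric mean), 6 Å cutoff with a
  smoothstep switch from 5 Å. Repulsion is unswitched (short-ranged).
- **fa_sol / fa_intra_sol** — Gaussian-exclusion implicit solvation:
  pair contribution (ΔG_i·V_j + ΔG_j·V_i)·exp(−(d/3.5 Å)²). Carbon and
  sulfur carry negative transfer free energies (burial favorable),
  nitrogen and oxygen positive.
- **fa_elec** — Coulomb with distance-dependent dielectric ε(r) = 10·r,
  over a small per-atom-name partial-charge table.
- **hbond_{sr_bb, lr_bb, bb_sc, sc}** — donor/acceptor heavy-atom
  geometry: depth 1.5 at 2.9 Å with σ = 0.35 Å, modulated by the angle at
  the acceptor base (ideal 120°). Short-range backbone means sequence
  separation ≤ 4 within a chain.
- **rama / omega / fa_dun / p_aa_pp** — cosine-series torsion
  preferences (φ/ψ, peptide-bond planarity, χ staggering, a small
  amino-acid-dependent φ preference).
- **pro_close**, **dslf_fa13**, **yhh_planarity**, **ref** — proline ring
  closure penalty, disulfide contact bonus, a placeholder (zero without
  hydroxyl hydrogens), and per-residue reference constants.

Covalent topology is intra-residue distance detection at build time plus
the backbone C(i)–N(i+1) link only; pairs within three bonds are excluded
from nonbonded terms. Restricting inter-residue bonds to the backbone is
deliberate: clashing atoms in unrefined models can approach covalent
distances and must stay visible to the repulsive term.

Pairwise terms are split half/half between participating residues for the
per-position decomposition, which makes the decomposition exactly
conservative. Peptide-only scoring keeps terms with at least one peptide
atom (peptide–groove pairs attributed fully to the peptide); such scores
are often positive — a strained ligand in a favorable groove is the
expected regime, and the sign convention (more positive peptide = more
energy released on receptor binding) is part of the hypothesis the
pipeline encodes.

This backend is approximate by construction. It preserves the term
taxonomy and semantics the classifier consumes; it does not reproduce any
external program's numbers. Term tables computed with external modeling
software can be injected via the TSV import backend
(`energy.load_breakdown_tsv`), and the registry (names, weights,
per-residue subset) is fully configurable.

## Surface area

Shrake–Rupley with a deterministic golden-spiral point set (default 960
points/atom, probe 1.4 Å): no RNG, so results are exactly reproducible,
at the cost of exact rotational invariance — rotating a structure changes
results only by sampling noise, about 1% of peptide SASA at 960 points and
about 0.2% at 3840. Hydrophobic classification is atomic: carbon and
sulfur hydrophobic, nitrogen and oxygen polar. Peptide aggregates are
computed in the context of the whole complex, so the groove occludes the
peptide; removing the groove can only increase per-atom areas.

## Threading and refinement

Threading keeps the template backbone bit-identical and rebuilds mutated
side chains from ideal internal coordinates (NeRF placement; bond lengths
and angles from standard values, aromatic rings closed exactly by
construction) in an all-trans rotamer. Groove atoms are never touched.

Refinement is Metropolis simulated annealing. Per sweep: one rotamer
proposal per movable residue (all peptide residues plus groove residues
with an atom within 4.5 Å of the peptide), drawn from a coarse
gauche−/gauche+/trans library with ±15° jitter, and one peptide-backbone
crankshaft move — a rigid rotation (≤ 8°) of the segment between two
peptide Cα pivots about their axis. Crankshaft moves preserve all bond
lengths exactly and keep the peptide termini anchored in the groove, which
is why they replace explicit loop-closure machinery; a bond-geometry check
rejects anything that would break the chain. Temperature cools
geometrically from 2.0 to 0.2 reduced units over the configured sweeps
(late-stage uphill acceptance is a few percent on fixtures). Move deltas
are evaluated with a local-energy shortcut (terms touching the moved
residues); this equals the full-score difference exactly because untouched
terms cancel, and a test asserts that equality. Each decoy records its
best-visited conformation. Defaults — 50 sweeps, 10 decoys, lowest 3
averaged — define the standard operating point; the consensus averages
unweighted terms, per-position terms and SASA over the kept decoys.

Register-shifted or length-changed binding modes are outside the sampled
move set; this limitation is inherent to threading onto a fixed-length
template. Groove backbone flexibility is likewise not sampled.

## Features and dataset

Candidate vectors: 18 complex terms in registry order, then per position
9 energy terms + total SASA + hydrophobic SASA → 117. The shipped
post-selection mask keeps all 18 complex terms and 7 per-position entries
(fa_atr, fa_rep, fa_sol, fa_elec, hbond_sc, both SASA terms) → 81. The
identity of the 7 surviving per-position terms is a configurable default,
not a fixed truth: the selection machinery
(`evaluation.eliminate_redundant_terms` — correlation pruning at |r| >
0.95 followed by backward elimination under a cross-validated AUC
tolerance of 0.002) can regenerate a mask from any dataset.

One-hot rows are ordered alphabetically by one-letter code. The
Wimley–White interface scale is packaged with literature provenance;
charged residues use ionized-state values, histidine the neutral value.
Negative = hydrophobic throughout, so "immunogenic more hydrophobic"
appears as negative mean differences.

Curation keeps 9-mers over the 20-letter alphabet, requires the target
allele (alias table; nonbinders exempt — they are defined by
incompatibility), and applies the response-frequency ≥ 50 evidence
threshold to the immunogenic pool. Labels: immunogenic → 1, self and
nonbinder → 0. Cross-pool duplicates keep the immunogenic assignment with
a logged warning. The per-position significance test is Welch's t by
default (a permutation test is available and serves as the oracle in the
test suite); raw p-values are reported alongside a Bonferroni column.

## Network and evaluation

Single hidden layer, tanh hidden units, logistic output, bias at both
layers; cross-entropy loss. These are conventional classification choices
— the hidden size (1–10) is the searched hyperparameter. Training is
Møller's scaled conjugate gradient (σ₀ = 5·10⁻⁵, λ₀ = 5·10⁻⁷) with
early stopping after 6 consecutive validation failures (max 1000 epochs);
the best-validation snapshot is returned. Initialization is symmetric
uniform scaled by fan-in, seeded. Standardization statistics come from the
training fold only and are stored with the model; serialization is JSON
with repr-round-trip floats, so save/load is bit-exact.

Nested 5-fold CV: pool-stratified folds (every pool dealt round-robin
after a seeded shuffle), rotated so each fold serves once as test and
once as validation. Immunogenic training examples are oversampled with
replacement to class balance — training portions only, asserted by a
leakage test. The hidden-size grid {2, 3, 4, 6, 8, 10} is searched
jointly over rotations; the winner's mean test AUC is the cross-validated
figure, and a final all-data refit (internal validation split for
stopping) yields the separately-reported total AUC. AUC is the exact
rank-statistic with ties counted ½.

## Synthetic data: what it does and does not show

The groove fixture is two ideal antiparallel α-helices (φ = −57°,
ψ = −47°) flanking an extended nonamer (φ = −139°, ψ = 135°; Cα–Cα
3.8 Å) at 13 Å axis separation — enough geometry for occlusion, contacts
and refinement to be meaningful, with no β-sheet floor or pocket
chemistry. The peptide generator plants a logistic immunogenicity model
in positional hydrophobicity with coefficients {p4: 1.8, p5: 1.0,
p7: 1.8, p8: 1.4} and intercept −1.0 on the negated Wimley–White scale
(chosen once to give a moderate, clearly recoverable effect: hydropathy
features reach cross-validated AUC ≈ 0.8, one-hot ≈ 0.6, against a
planted-null band of 0.45–0.55); anchor positions p2/p9 are aliphatic for
binder pools and forced non-aliphatic for nonbinders. Pool sizes default
to the real corpus proportions (2756 self / 155 immunogenic /
1044 nonbinder).

Passing tests on this material demonstrates that the machinery is correct
— contracts, determinism, leakage-freedom, oracle agreement, recoverable
planted signal — not that the desk energy function or the synthetic pools
quantitatively match real peptide/MHC thermodynamics or real epitope
statistics. Real-data performance requires real structures and corpora.

At desk scale the baseline comparison uses the hydropathy encoding as the
compact structure-derived representation: the generator plants its signal
in positional-hydrophobicity space, which full 3D modeling of hundreds of
peptides would recover only at orders-of-magnitude higher cost. The full
structural featurization is exercised end-to-end on small peptide sets
(`structimm model`, and the acceptance script's layout checks).

## Problem sizes

Tests and the acceptance script use scaled-down operating points chosen as
sensible desk-scale defaults: grooves with 12–24-residue helices, 2–10
annealing sweeps and 1–4 decoys in refinement tests, n = 500 corpora
(350/75/75) for cross-validation work, and the full 3955-record generator
only for bookkeeping. The null-band measurement averages three
independent label shuffles because a single shuffle's fold-mean AUC has a
standard error of ≈ 0.03 at this size.

## Known limitations

- The desk energy function is a taxonomy-faithful approximation; absolute
  energies are not comparable to any external package's output.
- Fixed lab-frame SASA sampling trades exact rotational invariance for
  exact reproducibility.
- No hydrogen placement: hydroxyl-orientation-dependent terms
  (yhh_planarity) are placeholders, and hydrogen bonds use heavy-atom
  geometry only.
- Threading cannot sample register shifts, bulged/shortened peptides, or
  groove backbone motion.
- The partial-charge and radius tables are minimal; ionization states are
  fixed.
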