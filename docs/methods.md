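# Methods

## Problem and model

The package treats fixed-backbone design as per-residue classification: every
residue of a target backbone is encoded from backbone geometry alone, and a
feed-forward network predicts which of the 20 standard amino acids occupies
that position. The assumption is that the identity of a residue is largely
determined by the *local* arrangement of nearby backbone segments — their
positions, orientations and torsions — so no global fold representation,
side-chain atoms or solvent terms enter the model.

## Feature construction

**Local frame.** For residue *i* with backbone atoms nᵢ (N), cαᵢ (Cα) and cᵢ
(C): u = normalize(c − n); a = n − cα; v = normalize(a − (a·u)u); w = u × v.
The frame is orthonormal and right-handed by construction; it is undefined
only when the three atoms are collinear or coincident (rejection or c−n norm
below 10⁻⁸ Å), which is rejected as degenerate.

**Neighbourhood.** "Proximal" is taken as Cα–Cα Euclidean distance; the 16
nearest residues are used, sorted ascending, exact ties broken by sequence
index, the target excluded from its own list. Chains shorter than 17 residues
zero-pad the missing rows and carry a boolean mask.

**Relative geometry.** Translations are tᵢⱼ = Oᵢ·(cαⱼ − cαᵢ), i.e. the
neighbour's Cα in residue *i*'s coordinates. Orientations are the unit
quaternion of R = Oⱼ·Oᵢᵀ (rows-as-basis convention, so Oⱼ = R·Oᵢ). R's
entries are direction cosines between the two bases, which is what makes the
quaternion invariant under any global rotation: both bases transform
identically and the transform cancels. The quaternion is scalar-first with
canonical sign (scalar component ≥ 0; when the rotation is within numerical
noise of a half-turn the scalar is ~0 and its sign is decided by roundoff, so
components below 10⁻⁶ are skipped and the first clearly nonzero component
sets the sign — this keeps the features stable under coordinate noise at the
cost of a discontinuity only on a measure-zero set).

**Torsions.** φᵢ is the C(i−1)–N(i)–Cα(i)–C(i) dihedral and ψᵢ the
N(i)–Cα(i)–C(i)–N(i+1) dihedral, signed by the standard convention
(verified against an independent implementation). Angles are encoded as
(sin, cos) pairs; an undefined angle — the first φ, the last ψ, or any
torsion spanning a chain break — encodes as (0, 0), a point off the unit
circle that the model can distinguish from every real angle. Chain breaks
are flagged where consecutive Cα atoms are further apart than 4.5 Å, beyond
any bonded Cα–Cα distance (trans ≈ 3.8 Å, cis ≈ 2.9 Å); this convention
covers crystal-structure gaps without dropping residues.

**Layout.** One residue's vector is its own 4-value torsion encoding followed
by 16 neighbour rows of 11 values (translation 3, quaternion 4, torsion
encoding 4): 180 values. No standardisation or whitening is applied —
translations are in Å and every other feature is bounded in [−1, 1]. The
layout version and quaternion convention are recorded in every feature file
header, and prediction refuses features whose layout does not match.

## Classifier and training

Architecture 180 → 64 → 64 → 64 → 20: affine + ReLU per hidden layer,
inverted dropout (p = 0.5) after each hidden activation, softmax output.
This gives 21,204 trainable parameters. Weights initialise from
U(±1/√fan_in). Training minimises mean cross-entropy with Adam (learning
rate 10⁻³, β₁ = 0.9, β₂ = 0.999, ε = 10⁻⁸) over shuffled batches of 4096
residues for up to 200 epochs; train loss, validation loss and validation
recovery are recorded per epoch and the best-validation-loss parameters are
returned, a reproducible stand-in for training "until convergence". All
randomness (initialisation, shuffling, dropout masks) flows from one seeded
generator, so identical inputs and seed give bit-identical parameters. The
forward/backward passes are written in numpy with analytic gradients; the
test suite checks them against central finite differences to 10⁻⁴ relative
error. No class weighting is applied despite amino-acid frequency imbalance.

Data are split at two levels: whole chains to a 10% test set, then 10% of
the pooled training residues to a validation set, both by exact-fraction
seeded sampling without replacement (a per-item Bernoulli draw would also be
defensible; exact fractions make split sizes deterministic). Residues whose
identity is not one of the 20 standard amino acids (plus MSE, treated as
Met) are featurised as neighbours but excluded as prediction targets.

## Synthetic data

The fixture generator grows backbones atom-by-atom from internal coordinates
(natural-extension reference frames) with frozen standard peptide values:
bonds N–Cα 1.458, Cα–C 1.525, C–N 1.329 Å; angles N–Cα–C 111.2°, Cα–C–N
116.6°, C–N–Cα 121.9°; ω = 180°. Requested φ/ψ are reproduced exactly by the
dihedral measurer (the central cross-module oracle). The learnability
dataset is 50 chains of 30 residues alternating ideal helix (φ = −57°,
ψ = −47°) and strand (φ = −120°, ψ = +120°) geometry; labels follow a
deterministic rule on the residue's own torsions (helical → Ala, extended →
Val), so the Bayes-optimal recovery is 1.0 and any shortfall is the model's.
Optional Gaussian coordinate jitter (σ ≤ 0.1 Å) makes positions
distinguishable without moving torsions across the rule's decision
boundaries.

What the generator does **not** emulate: loop/coil torsion diversity, the
20-class composition and frequency imbalance of real proteins, long-range
packing constraints, crystallographic noise and missing density, and the
many-to-one sequence–structure degeneracy that caps real-world recovery
around 25–35%. Passing the synthetic suite therefore demonstrates that the
geometry, features, gradients and training loop are correct — not that any
particular recovery level will be reached on experimental structures, which
requires training on a large nonredundant PDB corpus.

## Numerical and design choices

- Coordinates are Å throughout; residue indexing is 0-based positional, with
  author numbering kept only for reporting.
- PDB input only (no mmCIF); first MODEL only; per atom the
  highest-occupancy alternate location wins, ties to altloc 'A'; residues
  missing any of N/Cα/C are dropped with a warning.
- Dihedral range is (−π, π], with −π folded onto +π.
- Argmax decoding with ties to the lowest class index; no temperature or
  sampling — one designed sequence per backbone.
- Headline recovery pools residues across chains; per-chain recoveries are
  also reported (the pooled value equals their residue-weighted mean).
- Problem sizes in the test and acceptance suites (50 × 30-residue chains,
  ≤ 50 epochs, 200-instance oracle sweeps) were chosen to exercise every
  code path at desk scale with seconds-level runtimes.

## Known limitations

Training is CPU numpy: fine at fixture scale, slow for corpus-scale training
(a GPU port would swap the `model` module only). No hyperparameter search is
included — only the selected 3 × 64 architecture. Sequence-identity culling
of input chain lists is expected to be done upstream; only the
minimum-length filter is available locally.
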