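# Methods

## Problem and model

GFP-like proteins fold into an 11-stranded β-barrel around a central
α-helix. Fluorescent members autocatalytically cyclize the 65–66–67
tripeptide of that helix into the chromophore; this requires the immature
helix to sit in a *tight-turn* conformation whose signature is purely
geometric: the canonical i→i+4 main-chain hydrogen bonds around the triad
are broken and the backbone amide nitrogen of the cyclizing glycine (67) is
positioned near the carbonyl carbon of residue 65. Non-fluorescent GFP-like
proteins keep a regular α-helix there. The package quantifies which
conformation a structure is in and feeds the measurements into standard
two-group statistics and sparse classification.

All geometry is computed on the helix window defined by reference positions
60–74 (avGFP author numbering), located in each target through a multiple
sequence alignment containing the reference sequence. The backbone atom set
is the four non-hydrogen main-chain atoms N, CA, C, O per residue; CB is
excluded.

### Measurements

1. **Helix-overlap RMSD.** For two windows covering the same reference
   positions, atoms are paired N, CA, C, O per residue in window order and
   superposed by the closed-form Kabsch solution (SVD of the 3×3
   cross-covariance; the smallest singular direction is sign-flipped when
   needed so the rotation is proper, det = +1). Degenerate inputs (size
   mismatch, < 3 points, collinear sets, i.e. cross-covariance rank < 2)
   raise distinct errors. When a reference window is a subset of the
   target's (see "mature reference" below), the comparison is restricted to
   the reference's positions for *every* target, keeping atom counts equal
   across the cohort.
2. **Tight-turn distance.** Default atom pair N(67)→C(65), the
   nucleophilic-attack distance of the cyclization step. The mechanistic
   literature depicts but does not name the exact atom pair, so the
   definition is configurable as any (position, atom)–(position, atom)
   pair.
3. **HD1–HD11.** Plain Euclidean O(i)→N(i+4) distances (no
   angle or energy criterion — the upstream measurement tables are distance
   tables); HDk spans reference positions 59+k → 63+k.

### Sequence-level triad check

A chromophore additionally needs the right residues: glycine at the
cyclizing position, an aromatic residue at 66, arginine at 96. The aromatic
set defaults to {F, Y, W, H} (histidine is aromatic and supports
chromophore formation in blue variants); the glycine position defaults to
67 because the triad is 65-X/66-aromatic/67-Gly and it is residue 67 whose
amide attacks — some texts write "Gly65" for the same residue under a
different counting convention, so the position is configurable. A gap at a
checked position fails the check rather than erroring.

### Statistics

- **Group summaries**: mean, sd (ddof = 1), and five-number summary with
  type-7 (linear interpolation) quartiles, the convention of standard
  boxplot software.
- **Welch two-sample t-test**: unequal-variance t with Welch–Satterthwaite
  degrees of freedom, two-sided p (delegated to scipy).
- **Threshold rule**: one-feature classifier on the helix-overlap RMSD
  against the mature reference. Default cutoff = midpoint of the class
  means; a `minerror` mode minimizes training misclassification with ties
  broken at the midpoint of the tied interval. The class side is inferred
  from the class means (chromophore formers sit closer to the mature
  helix); a value exactly at the cutoff is assigned `can_form`.
- **Lasso logistic regression** on all fifteen features, response
  `can_form` = 1. Logistic (not linear) regression is used because the
  response is binary; features are standardized internally and constant
  features dropped with a recorded warning. The per-sample L1 penalty λ is
  chosen by stratified 5-fold cross-validated binomial deviance over a
  descending geometric grid (default 20 points, 1 → 1e-4), seeded; the full
  coefficient path is retained. Coefficients are reported on the original
  feature scale together with the standardization record. The solver is
  scikit-learn's saga; because the intercept is unpenalized, it is polished
  after each fit by a one-dimensional Newton solve of its score equation
  (a no-op when the solver has converged, an exactness fix in the strong-
  penalty limit where the null model's intercept must equal the class
  prevalence log-odds). On perfectly separable cohorts the weakly penalized
  end of the path stops at the iteration cap with large finite
  coefficients — expected behaviour for L1-logistic under separation, and
  harmless since penalty selection never picks those fits.

## Synthetic cohorts

The generator emulates the study design the statistics are meant for: two
conformational classes of 15-residue helix windows, numbered 60–74.

- **Construction**: natural-extension (NeRF) placement from per-residue
  (φ, ψ, ω) with fixed Engh–Huber bond lengths/angles (N–CA 1.458, CA–C
  1.525, C–N 1.329, C=O 1.231 Å; N–CA–C 111.2°, CA–C–N 116.2°, C–N–CA
  121.7°, CA–C=O 120.8°). Carbonyl O is placed in the peptide plane anti to
  the next residue's N. Torsions re-measured from the built coordinates
  match the inputs to < 1e-6°.
- **Classes**: `ideal_helix` (φ = −57°, ψ = −47°, ω = 180° throughout;
  label `cannot_form`) and `kinked_helix` (same, with the kink block at
  positions 64–67 set to φ = −80°, ψ = +10°; label `can_form`). The kink
  torsions are a qualitative choice: they open HD3–HD7 beyond 4.5 Å while
  leaving flanking H-bonds helical, reproducing the broken-H-bond signature
  of the precyclized conformation; nothing downstream depends on their
  exact values.
- **References** (noise-free): regular helix (regular-helix crystal role),
  full kink (precyclized crystal role), and a *mature-helix* reference
  built with a damped kink (70 % amplitude: φ = −73.1°, ψ = −7.1°). The
  damping encodes the empirical fact that the formed chromophore keeps most
  of the tight-turn distortion: the precyclized conformation lies much
  closer to the mature helix than a regular helix does. With this choice
  the class means of RMSD-vs-mature come out near 0.8 Å (kinked) and
  1.6 Å (regular) — the same scale as real predicted-structure cohorts.
- **Noise**: independent isotropic Gaussian displacement, sd 0.2 Å per
  coordinate by default, standing in for predictor variability. Member
  seeds are `spec.seed + index` over the concatenated cohort; the stream is
  numpy's PCG64 (`default_rng`), recorded in the cohort object.
- **Design sizes**: 21 `can_form` vs 23 `cannot_form` by default, matching
  the screened cohort the statistics layer mirrors.

What the generator does **not** emulate: the surrounding β-barrel,
side-chains, sequence diversity (members are all-alanine), correlated
predictor errors, or partial kinks. Passing tests therefore demonstrate the
correctness of the measurement and classification machinery under a clean
two-class geometry, not the discriminability of real predicted structures —
that is what the external-data acceptance checks are for.

## Numerical and I/O choices

- PDB parsing via gemmi; hydrogens, HETATMs and waters dropped; alternate
  locations resolved by highest occupancy, ties by lowest altloc label;
  model 1 by default (AI servers rank model 1 best); author residue
  numbering kept verbatim; insertion codes part of residue identity.
- Backbone extraction is strict: a requested residue that is missing or
  lacks any of N/CA/C/O raises (silently shrinking the window would corrupt
  superposition pairing). Consecutive CA–CA distances are checked against
  [2.7, 4.3] Å to catch mis-mapped or gappy models; the check is
  configurable and disabled on the synthetic route, where injected 0.2 Å
  coordinate noise legitimately exceeds the bound.
- Window mapping is strict (all 15 positions) by default, since
  superposition needs equal atom counts; a permissive mode keeps the mapped
  subset and records it.
- Distances are written to 3 decimals in CSV outputs (PDB fixed-column
  precision); superposition tolerances are stated per test (proper rotation
  to 1e-9, oracle agreement to 1e-3 Å).
- Per-target fingerprint failures do not abort a cohort run; they are
  recorded in the run log and reflected in the exit status.

## Problem sizes

The shipped analyses run on 44-member cohorts (the study design) and
20-seed repetitions for the classification-recovery results; superposition
oracle checks use 50 random 10-point instances. These sizes were chosen to
characterize the estimators well while keeping any run of the full suite a
matter of minutes.

## Known limitations

- The tight-turn atom-pair definition is an interpretation of the
  mechanism's depiction; alternatives are configurable but not validated
  against an external measurement set.
- The mature-reference handling for a real chromophore-bearing crystal
  (backbone of the modified triad deposited as a single HETATM residue)
  uses the subset-window fallback (positions 60–64, 68–74) rather than
  attempting to pair chromophore atoms to two residues' backbones.
- mmCIF input is not supported; lasso coefficient values (as opposed to
  which features are selected) depend on the penalty grid and fold seed, as
  in any cross-validated sparse model.
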