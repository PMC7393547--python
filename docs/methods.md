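# Methods

## Candidate sites and labels

A candidate cleavage site is any peptide bond of a substrate chain.
Each candidate is represented by the 8-residue window P4–P4′ around the
scissile bond; P1 is the residue N-terminal to the bond, indexed
0-based internally and 1-based in annotation files and prediction
tables (the MEROPS convention). Windows extending beyond the chain are
padded with a gap symbol that carries its own attribute category, so
terminus effects are learnable rather than discarded. Each candidate
site is one length-8 observation chain for the CRF; training labels are
homogeneous along the chain (all-cleavage for positive sites,
all-non-cleavage for negatives), and the prediction score is the
posterior marginal of the cleavage label at the P1 chain position.
This reproduces per-site classification while keeping the chain
coupling of the model; a whole-protein labelling mode could be added
behind the same `predict_site` interface.

## Structural descriptors

All descriptors are computed from raw coordinates rather than by
shelling out to the classical programs, using the defining geometry of
each quantity and the defaults of the tools that introduced them:

* **SASA** (Shrake–Rupley): probe 1.4 Å, 960 quasi-uniform sphere
  points per atom (golden-spiral quadrature; isolated-sphere error is
  well under 2%). Atom radii are element-keyed van der Waals values;
  unknown elements get the carbon radius with a log message. Hydrogens
  in the input are dropped at parse time so the radii table and the
  B-factor averages refer to heavy atoms consistently.
* **Accessibility categories**: all-atom, side-chain, main-chain
  (N/CA/C/O/OXT), non-polar side chain (C/S atoms) and polar side
  chain (N/O atoms); glycine's Cα counts as side chain, matching the
  reference-tool convention. Relative accessibility divides each
  category by the residue type's extended-tripeptide reference area
  (one table of total reference areas is used for all five categories;
  downstream the values are discretized per feature with bin edges fit
  on training data, so only the cross-residue-type normalization
  matters, not the per-category scale). Residue types without a
  reference ('X') report absolute values only.
* **Secondary structure**: Kabsch–Sander style. Backbone amide H is
  imputed from the previous residue's C=O geometry; an H-bond exists
  when the electrostatic energy 0.084·332·(1/r_ON + 1/r_CH − 1/r_OH −
  1/r_CN) kcal/mol is below −0.5. Helices require two consecutive
  n-turns; bridges use the standard parallel/antiparallel patterns and
  may span chains; the 8 classes collapse as H/G/I → helix, E/B →
  strand, else coil. Chains shorter than three residues and residues
  with missing backbone atoms are coil.
* **Torsions**: IUPAC sign convention, values in (−180, 180]; chain
  continuity requires C(i)–N(i+1) < 2.5 Å, and angles across breaks or
  degenerate geometry are missing, not exceptions.
* **Half-sphere exposure**: radius 13 Å. The HSE-A split uses the
  pseudo-Cβ direction from neighbouring Cα positions (falling back to
  the real/ideal Cβ direction at chain termini); the HSE-B split counts
  neighbouring Cβ atoms (ideal Cβ constructed from backbone tetrahedral
  geometry where absent) along the Cα→Cβ direction. CN counts
  neighbouring Cα atoms, so HSEAU + HSEAD = CN exactly.
* **Depth index**: distance of a buried atom to the nearest
  solvent-accessible atom (SASA > 0); exposed atoms have depth 0.
* **Protrusion index**: in a 10 Å sphere, cx = (V_sphere − V_int) /
  V_int with V_int = (atoms within the sphere) × 20.1 Å³, clamped so
  cx ≥ 0.
* **Hydrogen-bond counts**: geometric criterion (donor–acceptor
  distance < 3.9 Å; D–H…A angle > 90° where an H position is known —
  imputed for backbone amides, waived for side-chain donors). Bonds
  are credited to both partner residues; intra-residue pairs and
  sequence-adjacent backbone–backbone pairs are excluded.
* **B-factor / packing**: mean heavy-atom B-factor per residue;
  packing is the heavy-atom count within 8 Å of the residue centroid
  divided by the sphere volume (atoms/Å³). The packing definition is a
  local-density stand-in chosen here, since the quantity has no single
  canonical formula.

Per-residue values are means over the residue's atoms where the
underlying quantity is atomic (SASA categories aside, dpx and cx).
Missing values (termini, missing atoms) propagate as an explicit NA
category downstream, never as silent zeros.

## LOWESS smoothing and discretization

Each structural descriptor's 8-value window profile may be smoothed by
locally weighted linear regression before binning. For position i
(1-based in the 8-vector) a window S of positions is selected — the
interior window [i−r, i+r], or a boundary window [1, 2r] (left) or
[8−2r, 8] (right) when the interior window would leave the vector; all
windows are clipped to [1, 8]. Tricube weights w = (1 − (|i−j|/h)³)³,
clamped to [0, 1], use a case-dependent normalizer h (the window
half-width plus one: 2r−i+1 left, i−(8−2r)+1 right, 2r+1 interior).
The smoothed value is the weighted least-squares line through the
window evaluated at i; a window with zero weighted variance falls back
to the weighted mean. Constants and exact lines are reproduced to
floating-point accuracy for every range, and the smoother is
shift-equivariant — both properties are enforced by tests against an
independent weighted-least-squares oracle. The boundary-window weight
normalizers are isolated in one helper (`_window_and_weights`) so an
alternative reading is a one-line change.

Smoothed values are discretized into equal-width bins spanning the
[min, max] of the *training* values only; the edges are frozen into the
model and prediction-time values are clipped to the extreme bins.
Boundary values go to the upper bin; one bin means no edges (the
feature degenerates to a constant attribute, effectively disabling it).
Secondary-structure classes enter as three 0/1 indicator profiles per
window so that LOWESS operates on numeric vectors; unsmoothed they
discretize trivially.

Smoothing is applied per structural feature independently; sequence and
chemical-group attributes are never smoothed. The per-feature
(range, bins) pair defaults to (2, 5) and can be optimized by
cross-validated AUC over the 5 × 10 grid — sequentially, one feature at
a time in a fixed order with all other features held at the default,
using the same seeded fold split for every candidate, ties broken
toward fewer bins and then a smaller range. The sequential protocol
was chosen for tractability over a joint search of 50^k configurations.

## CRF training and inference

Unigram features pair every position-tagged attribute (e.g.
`res[P2]=V`, `cn[P1']=b3`) with a label; transition features pair
adjacent labels, with a distinguished start state. Attributes unseen
at training time contribute nothing at prediction (zero-weight
semantics). The penalized objective is NLL = −Σ log p(y|x) +
‖λ‖²/(2σ²) with σ² = 1 by default; the penalty is not rescaled by the
number of instances, so duplicating every instance changes the optimum
only through the relative weight of the penalty. Optimization is
L-BFGS from λ = 0 (the objective is convex, so training is
deterministic), gradient tolerance 1e−5, at most 300 iterations
(training) or fewer inside cross-validation folds where noted.
Forward–backward, Viterbi (ties toward the non-cleavage label) and the
gradient are all validated against brute-force enumeration of the 256
label sequences and central finite differences.

Models serialize to a single JSON file (weights, vocabulary, smoothing
and bin state, protease name, the stored 99%-specificity threshold,
training metadata); identical content yields byte-identical files.
The Sp-99% threshold stored at training time is computed on the
training-set scores, which is optimistic for truly novel substrates; it
is a reporting convenience, not a calibrated error rate.

## Dataset assembly

Annotations follow a MEROPS-style TSV schema (substrate id, protease,
1-based P1 position, substrate sequence, optional PDB id/chain).
Substrate-to-structure mapping uses pairwise global alignment with a
95% identity acceptance threshold, and requires both the P1 and P1′
columns to align to structure residues; a large-scale sequence-database
search is out of scope, so the caller supplies the (substrate,
structure) pairing. Only X-ray structures are retained. Negatives are
drawn uniformly without replacement (seeded) from non-annotated
candidate positions with full window coverage, in equal number to the
positives, from a global pool across the mapped substrates. Redundancy
filtering is a built-in greedy longest-first clustering at a pairwise
identity threshold (e.g. 0.7 for training sets, 0.3 for independent
tests); an external clustering tool can be substituted upstream.

Cross-validation is stratified k-fold, re-randomized per repeat from
the seed; all preprocessing state (smoothing, bin edges, vocabulary) is
fitted inside each training fold, which a leakage test enforces by
corrupting held-out profiles. AUC is the primary measure (tie-aware
trapezoid, equal to the rank statistic); Sn, Sp, precision, accuracy
and MCC are reported at a 0.5 cutoff, with undefined ratios reported as
missing (MCC's zero denominator maps to 0 by convention). Feature
combinations are compared by a paired two-sided t-test over per-repeat
mean AUCs (paired because the same fold splits are used; degenerate
zero-variance cases return p = 1 for identical inputs and p = 0 for a
constant shift).

## Synthetic data

The fixture generator grows ideal backbones residue by residue (NeRF
placement with standard bond lengths and angles): helices at
(φ, ψ) = (−57°, −47°), strands at (−119°, 113°), coil drawn from a
polyproline-II-like region (φ ∈ [−90°, −65°], ψ ∈ [120°, 160°]) so coil
neither forms helical H-bond patterns nor pairs into sheets. Only
N/Cα/C/O and an ideal Cβ are built — side chains beyond Cβ are not
modelled, so descriptors that would touch side-chain atoms degrade
gracefully to Cβ-level approximations, and fixture-derived expected
values are stable. B-factors are drawn per residue from a core model
(mean 15 Å², sd 3) in helix/strand and a loop model (mean 45 Å², sd 8)
in coil, emulating the elevated mobility of loops.

Default study conditions: 40 substrates of ~48 residues, loop fraction
0.35, one planted cleavage site per substrate. Depending on the signal
mode, positives carry the DEVD motif at P4–P1 and/or sit centred in a
coil segment; the manifest records signal-violating negative candidate
positions (non-coil placement for structural signal, non-motif windows
for sequence signal) so downstream sampling can respect the design.
All randomness derives from the spec seed; identical specs produce
byte-identical files.

What passing tests on these fixtures does and does not show: the
fixtures have ideal geometry, a single chain, no side chains, no
missing residues and a perfectly clean signal, so they demonstrate that
the pipeline recovers a planted sequence/structural signal and that the
structural channel carries information the sequence channel cannot see
— not that the model reaches any particular accuracy on real
crystallographic data, where descriptor noise, disorder and annotation
errors dominate.

## Problem sizes and numerical choices

Cross-validation defaults to 10 repeats of 5 folds; the synthetic
benchmarks use 40 substrates (80 windows after 1:1 negative sampling),
which keeps a full 10 × 5-fold comparison of two presets to a couple of
minutes on one core while leaving the paired t-test well powered for
the large effect the structural fixtures produce. The
label-permutation null is averaged over several independent
permutation draws because a single draw's AUC varies substantially at
n = 80 (windows of one substrate share descriptors). Degenerate inputs
are handled, not raised: constant training features collapse to a
single bin with a warning, degenerate dihedrals and smoothing windows
fall back to missing values and weighted means respectively.

## Known limitations

* The solvent-excluded (molecular) surface is not computed; the
  solvent-accessible surface serves all accessibility features.
* The secondary-structure assignment implements the core
  Kabsch–Sander patterns (helices, bridges/ladders, turns, bends) but
  not every tie-break of the reference implementation; fixtures with
  ideal geometry are assigned identically, real structures may differ
  in edge cases.
* Sites are classified independently per window; correlations between
  nearby cleavage sites of one substrate are not modelled.
* mmCIF input, NMR/EM model handling and external-tool adapters
  (DSSP, Naccess, MSMS, HBPLUS) are not implemented; the built-in
  descriptor path is the only path.
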