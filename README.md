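# cleavecrf

Protease-specific substrate cleavage-site prediction from protein 3D
structures (with a sequence-only variant), built on a linear-chain
conditional random field over windowed sequence, chemical-group and
structural features.

## The problem

Proteases hydrolyse the peptide bond between the P1 and P1′ residues of
their substrates. Which bonds a given protease cleaves is determined
both by the local sequence around the scissile bond (the P4–P4′ window)
and by the local 3D context — cleavage sites sit preferentially in
flexible, solvent-exposed loop regions. `cleavecrf` scores every
candidate scissile bond of a substrate by combining:

* **Sequence features** — one-hot residue identities over the 8-residue
  P4–P4′ window (8 × 20 = 160 dimensions);
* **Chemical-group features** — each residue mapped to one of eight
  chemical groups (sulfur C/M; aliphatic A/G/P and I/L/V; acidic D/E;
  basic H/K/R; aromatic F/W/Y; amide N/Q; hydroxy S/T; 8 × 8 = 64
  dimensions);
* **Structural descriptors** — computed per residue directly from
  atomic coordinates: five categories of absolute and relative
  solvent accessibility, secondary structure (8 classes collapsed to
  helix/strand/coil), backbone torsions φ/ψ, half-sphere exposure
  (CN, HSEAU/HSEAD/HSEBU/HSEBD), depth index (DPX), protrusion index
  (CX), hydrogen-bond counts, mean B-factor, and local packing density.

Each structural descriptor forms an 8-value profile over the window.
Profiles are smoothed by **LOWESS** (locally weighted linear regression
with tricube weights, smoothing range 1–5) and discretized into
equal-width bins (1–10), because the CRF uses Boolean (indicator)
feature functions that require categorical attributes.

## The model

A linear-chain CRF over binary labels y ∈ {non-cleavage, cleavage}
assigns

p(Y|X) = exp( Σᵢ Σₖ λₖ fₖ(yᵢ, yᵢ₋₁, xᵢ) ) / Z(X)

with indicator feature functions fₖ over (attribute, label) pairs and
label transitions. Training maximizes the L2-penalized conditional
log-likelihood (convex; deterministic L-BFGS from λ = 0); a candidate
site's score is the posterior marginal of the cleavage label at the P1
position, computed by forward–backward. Per-feature smoothing ranges
and bin counts can be optimized by cross-validated AUC over the
5 × 10 grid.

Five feature-combination presets are available: `seq`, `seq_chem`,
`seq_chem_real` (raw structural values), `seq_chem_smooth` (the full
structure-aware model) and `seq_chem_smooth_dssp` (smoothing only the
secondary-structure-derived descriptors).

## Worked example

Generate a synthetic benchmark (40 substrates with a DEVD motif planted
at coil-centred cleavage sites), train a structure-aware model, and
scan a substrate structure:

```bash
cleavecrf synth --outdir demo --n-substrates 40 --signal-mode both --seed 7
cleavecrf train demo/annotations.tsv --structures-dir demo \
    --preset seq_chem_smooth --out-model demo/model.json --seed 7
cleavecrf predict demo/model.json --pdb demo/SYN000.pdb --chain A \
    --out demo/SYN000.scores.tsv
```

The train step prints

```
model written to demo/model.json (training AUC 1.0000)
```

and the prediction table has one row per candidate P1 position; around
the true planted site of `SYN000` (P1 at position 16) it reads:

```
substrate  p1_position  window    probability  high_confidence
SYN000     15           ADEVDDLT  0.403084     False
SYN000     16           DEVDDLTH  0.997595     True
SYN000     17           EVDDLTHH  0.947685     False
SYN000     18           VDDLTHHG  0.036792     False
```

`probability` is the CRF posterior that the bond after the stated P1
position is cleaved; `high_confidence` flags scores above the stored
99%-specificity threshold. Comparing presets by repeated
cross-validation (10 × 5-fold AUC plus pairwise paired t-tests):

```bash
cleavecrf evaluate demo/annotations.tsv --structures-dir demo \
    --presets seq,seq_chem_smooth --folds 5 --repeats 10 --seed 7
```

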