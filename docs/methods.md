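# Methods

## Problem and data model

Given an antibody–antigen complex, every chain group (antigen or antibody)
is flattened into one ordered atom list with a `residue_starts` index
vector, so the atom→residue mapping is total and surjective by
construction. Multi-chain antigens/antibodies are concatenated in file
order with a single continuous 0-based residue index; this keeps the
mapping abstraction simple but means rotary positions are discontinuous
across chain breaks — a known approximation (sequence-aligned indexing is
exposed as a config option but off by default, since the resolved-residue
ordering is what the model is trained on).

Epitope labels use the inclusive contact rule: residue *i* is positive
when its minimum heavy-atom distance to the antibody is ≤ 4.5 Å. The
boundary is treated as inclusive because conventional contact definitions
are inclusive and the boundary set has measure zero for real coordinates.
Interface sets (for attention-map analysis) use 8 Å over all atoms,
hydrogens included when present.

Cleaning removes solvent, ions and ligands; non-standard residues (MSE,
PTR, …) are *dropped with a warning* rather than mapped to parent amino
acids — users who care should pre-convert. Alternative locations keep the
highest-occupancy conformer (ties prefer altloc A). Missing-atom repair is
deliberately out of scope: the reader tolerates incomplete residues and
the pipeline proceeds; repair belongs to an external preprocessing step
(e.g. a PDBFixer run) before `epipoint preprocess`.

## Features

Atomic (11 dims): coordinates, element one-hot (C, N, O, S, H; anything
else in a standard residue is rejected), and a local surface normal — the
smallest-eigenvalue eigenvector of the covariance of the k = 16 nearest
atoms, oriented away from the chain centroid, with a centroid-direction
fallback for rank-deficient neighbourhoods. Local PCA is the standard
point-cloud normal estimator; k is config-exposed.

Residue (62 dims), all scaled into [0, 1] so that masked-feature
corruption can draw uniform replacements from one common range:

* amino-acid one-hot, columns alphabetical by 3-letter code;
* PSSM: PSI-BLAST ASCII log-odds squashed by the logistic 1/(1+e^-x).
  When no PSI-BLAST profile exists, a substitution profile (the BLOSUM62
  row of the residue's amino acid, squashed identically) stands in and the
  dataset metadata flags it;
* solvent accessibility: Shrake–Rupley ASA (probe 1.4 Å, heavy atoms,
  via biotite) as (absolute scaled by the largest residue maximum,
  relative to the residue-specific maximum, clipped to [0, 1]). The
  (absolute, relative) pair is the only standard 2-dim accessibility
  descriptor;
* neighbour composition: normalized amino-acid histogram of residues
  whose Cα lies within 10 Å (uniform row for isolated residues, heavy-atom
  centroid when Cα is missing). Definition and radius are config-exposed.

PLM embeddings (480-dim antigen / 512-dim antibody by default) are
consumed from plain numeric tables, never computed.

## Architecture

RHEM: atom MLP 11→32→64 with GELU, max-pool per residue; fusion MLP only
when a PLM block is present (otherwise f_fused = f_res verbatim); embed
MLP (64+62)→128→128; learnable positional table, zero-initialized so the
additive-identity property is exact at initialization. Widths are not
fixed by the published description (supplement-level detail); the defaults
are sized for CPU work and fully config-exposed. Coordinates are centred
per chain before entering the atom vector (absolute position is
physically meaningless); the flag is recorded in dataset metadata.

Encoder: 4 pre-norm blocks, d_model = 128, 4 heads, MLP ratio 4, dropout
0.1, a final LayerNorm after block 4 (common pre-norm practice; recorded
here so ablations are reproducible). RoPE uses base 2048 and the
0-based resolved-residue ordinals. Antigen and antibody pass through the
*same* parameter objects.

Decoder: one cross-attention block (the update equations describe a
single block; stacking is configurable), no self-attention, no positional
terms inside cross-attention — hence exact permutation equivariance in
antibody residue order. Site head: 2 × 256 fully connected layers with
LN/ReLU/Dropout, then linear + sigmoid.

## Training

Both stages use AdamW (lr 1e-4, weight decay 0.05), linear warm-up then
cosine decay. The published schedule (pretraining 300 epochs / warm-up
10 / batch 96; fine-tuning 400 / 100 / 64) is available as the `paper`
preset; the default `desk` preset (20 / 2 / 4 and 40 / 10 / 4) is what the
tests and the worked example use — chosen as the smallest schedule at
which the synthetic benchmark is reliably learned.

Pretraining masks 50 % of residues per chain independently; one Bernoulli
draw per masked residue selects zero-fill (p = 0.2) for all three target
blocks jointly versus per-block uniform refill (p = 0.8) — the corruption
branches operate at residue level, and a random one-hot keeps the
amino-acid block in-distribution. Neighbour composition is never masked.
Masks are re-drawn every batch (standard BERT practice). Loss weights
default to λ_aa = λ_sol = λ_pssm = 1 (no published values; config-exposed).

Augmentation: Gaussian jitter of coordinates (σ = 0.1 Å) and normals
(σ = 0.05, renormalized), independent Haar rotations of the two chains,
and pretraining-only Gaussian noise (σ = 0.02) on neighbour composition
and solvent accessibility, clipped to [0, 1]. PSSM noise is excluded (only
composition and accessibility are named as noise targets). The noise
magnitudes are not published; these defaults are small fractions of each
quantity's natural scale and are config values, not tuned constants.
Because the two chains rotate *independently*, the mutual binding pose is
destroyed; epitope labels are therefore computed before augmentation and
frozen — the model must infer the epitope from per-chain geometry and
cross-attended features, not from the docked pose.

Fine-tuning initializes RHEM + encoder from stage 1 and trains the whole
stack end to end (the weights are initialized from pretraining, not
frozen). Label smoothing ε = 0.1 (use is published, magnitude is not).
Class imbalance is handled purely by threshold selection on validation
MCC — the training loss stays plain BCE.

## Synthetic benchmark

The generator emulates the statistical skeleton the pipeline relies on:
chains as self-avoiding 3.8 Å random walks of residue centroids, 4–14
heavy atoms Gaussian-scattered (σ = 0.8 Å) per residue with plausible
element composition, an antibody translated along a centroid-to-surface
axis until ≈ 12 % of antigen residues are in contact (the typical epitope
fraction for chains of this size; per-complex tolerance ± 0.05), and
labels always re-derived by the real contact-labelling code. The
learnable signal is planted in solvent accessibility — epitope residues
draw relative accessibility from N(0.85, 0.08), background from
N(0.35, 0.15) — mirroring the biological prior that epitopes are
surface-exposed, and exercising both the feature and the geometry paths.

What passing the synthetic benchmark shows: the full two-stage pipeline
can extract a residue-level signal through RHEM, the shared encoder, the
cross-attention decoder and the threshold machinery, end to end, with all
invariants intact. What it does not show: performance on real antibody
repertoires — the generator has no side-chain chemistry, no realistic
fold geometry, no evolutionary signal in the PSSM, and its planted signal
is simpler than real epitope determinants.

## Numerical choices

* All computation in float64 on the package's own reverse-mode autodiff
  engine; analytic gradients are validated against central finite
  differences (relative error < 1e-4 on toy instances) in the tests.
* Max-pool gradients split equally across tied maxima (a valid
  subgradient; makes duplicate-atom idempotence exact).
* Softmax subtracts the (detached) row maximum for stability; GELU is the
  exact erf form.
* The MCC convention for degenerate confusion matrices (any zero
  marginal) is 0; AUC is reported as missing for single-class inputs.
* Threshold search scans the set of unique predicted scores plus {0, 1},
  which is the exact optimum for finite data; ties return the smallest
  threshold.
* Scale choices for the test suite and the worked example: 30 complexes
  of 40–70 antigen / 25–45 antibody residues (20 train / 10 held-out),
  desk schedules as above; the frozen-batch descent check uses 4 smaller
  complexes (20–30 / 12–20 residues) for 500 fixed-batch steps.

## Known limitations

* No mmCIF input, no structure repair, no protonation.
* Antibody-agnostic prediction and ensembling are out of scope; the model
  always conditions on a specific antibody.
* Hetero-multimeric antigens get one concatenated index space; inter-chain
  positional discontinuities are not specially encoded.
* The engine is CPU-only and sized for small models; the `paper` preset
  schedule is impractical without substituting a GPU framework.
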