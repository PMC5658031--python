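# Methods

## The reconstruction model

`prsda` implements template-based backbone reconstruction with a per-target
stacked denoising autoencoder (SDA). The premise is that a target protein's
structure can be recovered from the structures of its homologs alone: a deep
model is trained, for one target at a time, on an ensemble of perturbed
("decoy") conformations of the target's template structures, with the clean
template-native coordinates as the training label. Decoys play the role of
noisy data, the template natives the role of clean data; a model trained to
denoise this ensemble maps any crude conformation of the target into the
vicinity of the template fold.

A conformation of an L-residue protein is represented as a flat vector of
length L·(12+1): per residue, the x, y, z coordinates of the four backbone
atoms N, Cα, C, O (12 numbers), plus one residue-type channel. Residue types
are encoded as the 1-based alphabetical index of the one-letter code divided
by 20 (A → 0.05 … Y → 1.00; unknown codes → 0). Before encoding, all
structures are superposed into a common frame (the first template native) and
coordinates are normalized into the unit box by

    x_new = (x − x_min) / (x_max − x_min)

with a single isotropic scale N = x_max − x_min fitted jointly over the decoys
and the labels. One global scale (rather than per-axis or per-structure
bounds) means every pairwise distance shrinks by exactly 1/N, so geometry is
preserved up to a known factor and a single inverse transform returns model
output to Ångström space.

### Network

The network is a mirrored stack of tied-weight layers. Layer k holds one
weight matrix W and two biases; encoding is

    y = sigmoid(W x + b)

and decoding is the affine map

    z = Wᵀ y + b′

with no output nonlinearity (an optional [0, 1] clamp exists as a
post-processing flag, off by default). Three hidden layers are used by
default, with widths shrinking by the ratios 0.9, 0.8, 0.7 (floored to
integers): a 60-residue target has input width 780 and hidden widths
702, 561, 392.

### Training

Training is two-phase:

1. **Layer-wise denoising pretraining.** Each layer in turn reconstructs its
   clean input from a corrupted copy under mean squared error. Corruption
   zeroes coordinate channels independently with probability 0.3 (the
   residue-type channel is never corrupted at the visible layer); masking to
   zero mirrors the zero-fill convention for alignment gaps, so the model
   sees the same kind of missingness it must tolerate at test time.
2. **Supervised fine-tuning.** The full encode/decode stack is trained
   end-to-end by mini-batch SGD on a coordinate-RMSD objective,

       loss = sqrt( Σ_k |pred_k − label_k|² / n ),

   where the sum runs over the atoms of non-vacant residues (n counts atoms;
   the residue-type channel and zero-filled gap positions are excluded).
   Labels are the template-native feature vectors.

All gradients are analytic backpropagation, validated in the test suite
against central finite differences (relative error < 1e-5). Defaults: learning
rate 0.05 for pretraining and 0.01 for fine-tuning, batch size 20, 100
pretraining epochs per layer, 300 fine-tuning epochs, no early stopping (a
fixed epoch count keeps runs bit-reproducible). The RMSD objective has a
constant-magnitude gradient, so SGD decreases the residual by a roughly
constant decrement per step; the epoch budget is sized so that a 500-decoy
training set converges well past the accuracy of interest. Mini-batch order is
shuffled deterministically from the seed; identical configuration and seeds
reproduce checkpoints and output PDB files byte-for-byte.

Fine-tuning inputs are not corrupted by default (noise lives in pretraining
only); a flag enables it. Pretraining can be disabled entirely, leaving seeded
uniform ±sqrt(6/(n_in+n_out)) initialization.

### Test-time reconstruction

At prediction time an extended backbone of the target sequence is built at
fixed torsions (phi +135°, psi −135°, omega 180° by default), translated so
its centroid matches the training-frame centroid, normalized under the frozen
scale (values outside the training box are clipped into [0, 1] and logged),
passed through the network, and denormalized into a backbone structure
written as a standard PDB file. Any other crude conformation (for instance a
held-out decoy) can be supplied instead of the extended chain; when a
reference structure is given the input is superposed onto it first.

The +135/−135 torsion convention is kept as the primary default; the more
common extended-state convention (phi −135, psi +135) is available by passing
those values, since both are plain parameters.

## Templates, alignments, gaps

Template search and alignment are upstream, external steps: the package
consumes template PDB files plus an optional target↔template residue mapping
(`psiblast_command` prints the search command a user would run). A template is
mapped onto the target length by copying aligned residue coordinates,
discarding template overhang, and zero-filling unaligned target positions.
Zero-filled positions are flagged "vacant" and excluded from superposition
and from the training loss; whether such positions should instead participate
in the loss is untestable from first principles, and excluding them avoids
rewarding the network for reproducing an arbitrary fill value.

## Decoy generation

Decoy ensembles emulate the observable behaviour of dedicated decoy
generators: diverse, well-spread conformations whose CA RMSD to the native
covers a wide band (3–13 Å by default, matching the input spread of the
robustness experiment). Mechanism: 1–3 randomly chosen pivot residues receive
random phi/psi kicks applied as rigid rotations of the downstream chain about
the actual bond axes — this changes exactly the kicked torsions while
preserving every bond length and angle. The common kick magnitude is rescaled
iteratively until the decoy lands near a stratified target RMSD, so the
ensemble covers the band approximately uniformly (each third of the band
holds at least 20% of decoys). A rejection budget of 50·n attempts guards
against unreachable bands. 500 decoys are generated per template, 1000 when
only a single template is available. Externally generated decoy PDBs can be
imported instead; their RMSD annotations are recomputed on load.

## Synthetic natives

The fixture generator builds native-like backbones from ideal secondary-
structure torsions (helix −57/−47, strand −135/+135) with ~4° Gaussian
torsion jitter. Mixed-motif chains alternate helix and strand segments of
6–12 residues joined by 2–4 residue turns whose torsions are drawn from real
turn basins of the Ramachandran map, including left-handed conformations so
the chain can reverse direction; among the clash-free candidates drawn for a
seed, the most compact (smallest CA radius of gyration) is kept. This
produces 60-residue folds roughly 40–60 Å across — somewhat less compact than
a real globular 60-mer (no packing forces act on the backbone) but far from
the ~140 Å meanders that naive segment chaining yields.

What the generator does **not** emulate: side chains and packing, hydrogen-
bond registry between strands, sequence-dependent backbone geometry, and the
energy-based refinement of real decoy generators. Passing tests on these
fixtures therefore demonstrate that the learning machinery works as designed
— that a per-target SDA can collapse a wide-RMSD input ensemble onto its
label structure — not that the method attains any particular accuracy on real
proteins, which depends on template quality and alignment correctness.

## Metrics

RMSD is the plain root-mean-square deviation over paired atoms; superposition
(closed-form SVD least-squares fit with reflection correction) is applied
first where stated. GDT at cutoff c is the largest fraction of CA atoms that
can be brought within c Å of their native counterparts by a rigid fit; GDT-TS
averages cutoffs 1, 2, 4, 8 Å. Exact GDT requires an exponential subset
search, so the implementation uses the standard iterative heuristic — seed
fits from contiguous windows of length 3/5/7 and the full chain, re-fit on
atoms within the cutoff to a fixed point, then refine with fits on the k
nearest atoms for every k. The heuristic is exact on the constructed test
fixtures and on moderate-noise cases (verified against exhaustive subset
enumeration up to 12 residues); when many atoms sit near the cutoff boundary
it can undercount slightly, as any seeded GDT search does.

The paired t-test on per-target metric columns computes the usual statistic
with df = n − 1 and evaluates the two-tailed p-value from the regularized
incomplete beta function (continued-fraction form), cross-checked in the
tests against an independent statistical library. Zero-variance difference
columns are rejected rather than reported as p = 0. The "< 1 Å" counts over
benchmark tables use strict inequality; no printed table value lies close
enough to 1.0 for the choice to matter.

## The robustness experiment

`pipeline.robustness_experiment` re-creates, at desk scale, the experiment
showing that output quality is insensitive to the starting conformation: a
60-residue synthetic native is generated, 500 decoys spanning 3–13 Å train
the model, and 20 further held-out decoys spanning the same band are each
pushed through the trained network. Expected behaviour (asserted by the
acceptance tests at these sizes): every output lands below 2 Å CA RMSD to the
native, and the spread (max − min) of output RMSDs stays under 0.5 Å because
the trained network's output is dominated by the learned label rather than by
the input. Seeds are staged from one master seed (native, decoys, training,
held-out inputs use seed, seed+1, seed+2, seed+3). The full run takes a few
minutes on one CPU; problem sizes (60 residues, 500 decoys, default epochs)
were chosen as the smallest at which the banded decoy ensemble and the
network widths are representative of the full-scale procedure.

## Numerical choices and edge cases

- Superposition requires ≥ 3 non-collinear points; collinear inputs and
  all-equal coordinate sets (degenerate normalization scale) raise errors.
- The RMSD-loss gradient divides by the per-sample loss; samples already at
  zero loss contribute zero gradient rather than NaN. Non-finite losses abort
  training with a diagnostic.
- Dihedrals follow the right-handed (IUPAC) sign convention, returned in
  (−180°, 180°]; chain building uses NeRF-style sequential placement with a
  configurable bond-geometry table (N–CA 1.458 Å, CA–C 1.525 Å, C–N 1.329 Å,
  C=O 1.231 Å; angles N–CA–C 111.2°, CA–C–N 116.2°, C–N–CA 121.7°,
  CA–C–O 120.8°). The carbonyl O is placed in the sp2 plane at dihedral
  psi − 180°.
- PDB reading takes the first model and first altloc; a residue missing any
  backbone atom is an error in strict mode and is dropped with a log message
  in lenient mode. Writing uses fixed 80-column ATOM records, serials from 1,
  chain A; coordinates with |value| ≥ 10⁴ Å do not fit the fixed columns and
  are rejected.
- Model checkpoints are a small versioned container (magic string, JSON
  header with shapes/scale/seed/centroid/training log, raw little-endian
  float64 parameter blobs). Loading rejects wrong magic, truncation, or
  shape-inconsistent payloads.

## Known limitations

- The learned map is target-specific: one trained model serves one target
  sequence/length; there is no transfer between targets.
- With a single template and a constant label, the optimum is a constant
  output; the method's value on real data rests on multiple templates and on
  label variety, which the synthetic single-template experiments do not probe
  beyond the two-template bookkeeping tests.
- GDT is heuristic (see above); reported GDT can be a slight underestimate.
- No side chains, no mmCIF, no insertion codes, and no model ranking: one
  deterministic model per seed.
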