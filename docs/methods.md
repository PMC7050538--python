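# Methods

This note records the models and conventions the package implements,
the parameters that matter, and what the synthetic benchmark does and
does not show. The package is a library with narrative example scripts;
the importable API (plus `scripts/acceptance.py`) is the interface, and
no shell command wrapper is provided.

## Molecular graphs and pair fingerprints

Molecules are hydrogen-suppressed graphs: heavy atoms carry element,
formal charge and an attached-hydrogen count; bonds carry one of
single/double/triple/aromatic. A pair descriptor is
`type_a | d | type_b` with `d` the shortest bond-path length (computed
with scipy's sparse graph routines; unreachable pairs are infinite and
never counted). Fingerprint generation increments one descriptor per
unordered heavy-atom pair with `1 ≤ d ≤ max_distance`.

Conventions the original descriptor generators never published, fixed
here explicitly:

* **π electrons** (AP typing): a double bond contributes 1 π electron
  to each end atom, a triple bond 2, an aromatic bond 1. An aromatic
  ring carbon therefore types as `C(2,2)`.
* **BP rule table**, evaluated in fixed precedence: formal charge > 0 →
  cation; < 0 → anion; then N/O atoms are classified by
  donor/acceptor character — donor means the atom bears hydrogen,
  acceptor means oxygen, or nitrogen with an available lone pair
  (a π-engaged NH nitrogen, pyrrole-like, is donor-only) — donor-only →
  neutral donor, acceptor-only → neutral acceptor, both → polar; then
  carbon and halogens → hydrophobic; everything else → other. Under
  this table an sp3 amine nitrogen is polar (donor and acceptor), which
  is a defensible but not unique choice.
* **`max_distance` defaults to 7** bonds. The published descriptor
  definition caps the distance without stating the cap; 7 is in the
  range atom-pair implementations commonly use, and it is an explicit
  argument everywhere.

Because these conventions are package choices, vocabulary-level
agreement with any externally distributed descriptor files is not
claimed; correctness is instead established against a brute-force pair
enumeration oracle on random graphs.

## Activity tables and alignment

Tables are CSVs with a molecule-id column (`MOLECULE`), an activity
column (`Act`) and integer descriptor columns; descriptor-key names
contain commas and are CSV-quoted. Missing descriptor cells read as 0;
missing or non-numeric activities are an error naming the row, since an
activity cannot be imputed. Floats are written as `%.17g` and read with
pandas' round-trip parser so read∘write is exact.

Alignment takes the sorted union of the two splits' column sets and
zero-fills each side's missing columns: a column absent from a split
means the substructure occurred in no molecule of that split, so zero
is the true count, not an imputation. Activities are never rescaled or
centred — they are assay-defined log-scale quantities (pIC50, log D,
…) whose ranges are part of the problem.

The log-transform option maps counts x → log(1+x) (log alone is
undefined at the zeros that dominate count matrices) and never touches
activities.

## Network and training

The regressor is a fully connected ReLU network with a single linear
output neuron, written directly in NumPy: the architectures are small
enough that BLAS matrix products dominate and no framework features
(autodiff graphs, GPUs) are needed, and a from-scratch implementation
keeps every numerical choice visible and bit-reproducible.

* **Initialisation**: He-style fan-in-scaled normals (std √(2/fan_in)),
  zero biases, no pre-training.
* **Dropout**: inverted (scaled at train time), per hidden layer at the
  setting's rates, never on the input layer, never at evaluation. With
  inverted dropout the dropout-free forward equals the expectation over
  masks for a linearly read-out layer; a Monte-Carlo test asserts this.
* **Loss/optimiser**: mini-batch MSE, one Adam step per batch with
  α = 10⁻³, β₁ = 0.9, β₂ = 0.999, ε = 10⁻⁸ (the optimiser's standard
  constants; all exposed in `TrainConfig`). Inputs are raw counts, so α
  interacts with input scale; the defaults are kept throughout.
* **Batching**: molecules are reshuffled every epoch; the partial final
  mini-batch is trained on, giving ⌈n/batch⌉ updates per epoch.
* **Determinism**: a run seed spawns two named generator streams
  (initialisation; shuffling + dropout masks), so a (seed, data,
  setting) triple reproduces its trajectory bit for bit on one
  platform. Run *k* of a setting uses seed `base_seed + k`.

## Protocol and reporting

Test R² is computed after every epoch with dropout off; a run scores
its best epoch (first maximizer on ties), a setting scores the mean
over `n_runs` runs (default 5), and the grid report holds the
target × setting means with the Average column and per-target
Std. Dev. row recomputed from cells on demand. Best-epoch selection
reads the test trace and is therefore an oracle, not a blind-test
protocol; reports carry a final-epoch column alongside, and per-run
JSON logs (seed, setting, full traces) make every mean auditable.

R² uses the zero-variance convention: if either vector is constant the
correlation is undefined and the function returns 0 with a logged
warning, so a collapsed model scores worst instead of crashing a
1000-epoch run. Accumulation is double precision throughout.

## Synthetic data generator

The generator's reference conditions (the defaults of `SyntheticSpec`)
are 3000 train / 600 test molecules and 300 training descriptors — the
molecule-to-descriptor ratio of the mid-size real targets — with 90 %
zero entries, 80 % vocabulary overlap, shift strength 0.2 and activity
noise 0.3.

* **Counts**: column inclusion probabilities follow a 1/rank power law
  scaled (by bisection, so the expected zero fraction is exact) to the
  requested sparsity; included entries are 1 + NegBin(r, ·) with extra
  mean 2 and dispersion r (default 1, geometric-tailed). This mimics
  the few-ubiquitous / long-tail-of-rare profile of substructure counts
  without claiming to match any particular real target.
* **Vocabulary mismatch**: the test split observes a random
  `vocab_overlap` fraction of the training columns plus novel columns
  (late-appearing chemistry). Mechanism coefficients are nonzero only
  on the training vocabulary, so the clean signal is in principle fully
  recoverable from the training split; novel columns act as structured
  distractors. Real time splits are harsher — genuinely new chemistry
  carries activity the training data cannot reveal — so passing
  recovery tests here bounds optimism about real data.
* **Covariate shift**: test column frequencies are multiplied by
  exp(shift_strength · N(0,1)) per column.
* **Mechanisms**: `linear_logD_like` is an affine function of a sparse
  weighted count sum, standardised by its analytic moments (never
  data-fitted) and placed on a log D-like 0–5 scale.
  `single_index_nonlinear` squashes the same index into a pKi-like
  4.5–7.5 range and converts it to a measured pIC50 through
  IC50 = Ki·(1 + [S]/Km) with per-molecule log-normal [S]/Km (median 1,
  `jitter_sd` decades): assay-condition dependence as irreducible,
  structure-independent variation. `composed_multimechanism` passes
  three independent sparse indices through sigmoids and combines them
  as log10(r₁·(1 − 0.8·r₂)/(r₃ + 0.1) + 0.01) + 1 — an
  absorption/extraction/clearance-style composition — with
  heteroscedastic noise (sd scaled by 0.5 + r₃). Complexity claims are
  encoded only as an ordering between mechanisms, never as target R²
  values.
* **Censoring**: with `censor_floor` set, activities below the floor
  are emitted as exactly the floor, like assay panels that report
  everything beyond the measured concentration range as one constant.

## Problem sizes in tests and the acceptance script

Unit and acceptance runs use scaled-down networks (16–128 hidden
neurons) on the generator's desk-scale datasets, with mini-batches of
100 and 25; at a few thousand training molecules, a batch of 25 keeps
the updates-per-epoch count in the same regime as the full-scale
protocol's batches of 100 on tens of thousands. The miniature grid (2
targets × 3 settings × 2 runs × 30 epochs) and the mechanism comparison
(3 seeds × 30 epochs) establish protocol and report correctness and the
complexity ordering; their R² values are properties of the synthetic
conditions and are not comparable to any full-scale figures.

## Known limitations

* The BP donor/acceptor rules use local atom environments only; no
  tautomer or resonance perception, and sulfur/phosphorus land in
  "other".
* Aromaticity is taken from the input (bond orders in SDF/RDKit or the
  constructed graph); no aromaticity perception of its own.
* The generator draws descriptor columns independently; real
  substructure counts are strongly correlated (co-occurring fragments),
  which typically makes real problems easier for depth to exploit than
  the independent-column emulation.
* Best-epoch scoring leaks the test set by construction (it reproduces
  the benchmark's definition); use the final-epoch column for any
  honest-generalisation reading.
* Training is single-threaded NumPy; the full 13-setting grid at real
  data sizes (4000-neuron layers, 1000 epochs, 5 runs, 15 targets) is
  out of desk scope, which is exactly what the synthetic desk-scale
  path is for.
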