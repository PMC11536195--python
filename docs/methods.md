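# Methods

## Problem and model

Maleimides are donor–acceptor fluorophores whose absorption and emission
maxima shift with both alkene-carbon substitution (amino, dithio,
aminothio, alkoxy) and solvent polarity. `malphot` models the wavelength
of maximum absorption or emission, λ (nm), as a function of molecular
structure and solvent with a deliberately simple quantitative
structure–property regression:

- **Structure descriptor.** A 1024-bit binary extended-connectivity
  (Morgan/ECFP-style) fingerprint with bond radius 5, computed from the
  SMILES string alone — no 3-D geometry. Each atom's initial integer
  invariant hashes (element, formal charge, heavy-atom degree, attached-H
  count, ring flag); at each radius step the identifier is re-hashed with
  the sorted (bond order, neighbour identifier) pairs; identifiers that
  cover an already-seen atom set are dropped (smallest radius wins, then
  smallest identifier, making the result independent of atom numbering);
  surviving identifiers set bit `id mod 1024`. The hash is 32-bit FNV-1a,
  so fingerprints are bit-for-bit reproducible across platforms but do not
  share bit positions with any third-party toolkit; all tests therefore
  assert properties (permutation invariance, sensitivity, Tanimoto axioms,
  rank agreement with RDKit's Morgan similarity) rather than foreign bit
  patterns. Stereochemistry and isotopes are ignored; fingerprints are
  binary, not counted.
- **Solvent descriptor.** The static dielectric constant ε appended as a
  single real-valued input (element 1025). This captures only the
  averaged environmental effect — the same approximation implicit solvent
  models make — and deliberately ignores hydrogen bonding and other
  specific interactions; chloroform's well-known anomalously red readings
  are one consequence.
- **Regressor.** A feed-forward network with one hidden layer of 250 ReLU
  units and a single linear output, trained by mini-batch SGD (constant
  learning rate 1e-3, batch 32, momentum 0.9, L2 1e-4) for at most 2000
  epochs on a random 90/10 train/test split. "Iterations" are epochs over
  the training partition. Targets are centred and scaled internally and
  reported back in nm; the default ε transform is the identity (a z-score
  option exists behind `ModelConfig.eps_transform`, but the raw value
  converged at least as well in practice). Training stops early when the
  loss improves by less than 1e-7 over 50 epochs. Weight fitting delegates
  to scikit-learn's `MLPRegressor`; the fitted weights are extracted into
  `TrainedSpectralModel`, whose NumPy forward pass is the prediction path
  and is verified against a brute-force element-wise oracle to 1e-9.

Because SGD is stochastic, headline R² values are medians over several
reseeded runs (`train_model_multiseed`, default 10); single-run numbers
fluctuate by a few hundredths. R² uses 1 − SS_res/SS_tot about the
observed mean, with the zero-variance case defined as 0. An optional
validation split (`validation_fraction > 0`) enables early stopping for
over-fitting checks; it is off by default since the datasets involved are
small.

## Dataset schema and curation rule

A record is one (molecule, solvent) literature measurement: SMILES,
solvent name, ε, λ_abs and/or λ_em, substitution class, source tag. Rows
lacking a parsable structure, a resolvable solvent, or both wavelengths
are excluded, with per-row reasons reported. "Absorption" and
"excitation" maxima are stored as a single λ_abs field: the literature
this schema targets uses the terms interchangeably without stating whether
they always coincide, and the ambiguity is documented here rather than
resolved. Duplicate (molecule, solvent) rows are kept as distinct records.
Structures that parse but lack the five-ring maleimide core (N, two
carbonyl C, two alkene C) are kept but flagged. Class assignment inspects
only the exocyclic heteroatoms on the two alkene carbons (both S → DTM;
S + N → ATM; N only → AM; one S → monothio; O-ether only → alkoxy);
imide-N substitution never changes the class.

The shipped solvent registry (`data/solvents.yaml`) is case- and
whitespace-insensitive and carries the dielectric constants used
throughout (hexane 1.88, diethyl ether 4.33, chloroform 4.88, methanol
32.7, acetonitrile 37.5, plus standard 20–25 °C handbook values for other
common solvents).

## Synthetic-data generator

The generator fabricates datasets with the statistical structure of the
curated literature set so the entire pipeline is testable offline, with a
paired noise-free truth table. Its law is a test harness, not a
photophysics model:

    λ_abs(class, subs, ε) = base[class] + Σ δ_sub + amplitude[class] · g(ε)
    λ_em = λ_abs + Stokes[class]

with g(ε) = ((ε−1)/(ε+2)) / ((37.5−1)/(37.5+2)) — an Onsager-style
saturating response, monotone nondecreasing with g(1) = 0 and g(37.5) = 1,
chosen because measured maleimide trends keep rising at high ε while
remaining bounded. Default anchors (nm): base AM 361, DTM 395, ATM 385,
alkoxy 326; amplitudes 24 (20 for alkoxy); Stokes 82/62/72/70. These put
amino absorption near 367 nm in hexane rising to 385 nm at ε 37.5 (a
shift of ≈ 18 nm), mean dithio absorption near 410 nm over the default
solvent set, the amino-vs-alkoxy offset at 35 nm, and amino emission in
the 450 nm region. Substituent increments δ_sub are small (|δ| ≤ 3 nm) and
mean-zero within each fragment library so class means sit on the anchors.
An off-by-default `chloroform_anomaly` switch adds +8 nm in chloroform,
mimicking that solvent's consistently red readings.

Molecules are assembled from maleimide-core SMILES templates and a named
fragment library (12 amines, 4 thiols, 3 ethers, 5 imide-N caps — enough
distinct amino structures to draw 64 unique molecules at 66 % AM).
Defaults emulate the curated set: 64 molecules, class proportions
0.66/0.13/0.10/0.11 (AM/DTM/ATM/alkoxy), 2–6 solvents per molecule from
six common solvents, Gaussian noise σ = 5 nm on each wavelength (large
enough to be felt, small enough that test R² ≥ 0.8 is recoverable), one
seeded RNG stream for byte-identical reruns. Emission is clamped to stay
at least 5 nm red of absorption so every record satisfies λ_em > λ_abs.

What the generator does **not** emulate: real structural diversity beyond
the template space (fused rings, push–pull aromatics), heteroscedastic
literature noise, solvent effects beyond a single monotone ε response
(hydrogen bonding, specific solvation), correlated absorption/emission
errors, and reporting biases. Passing the recovery tests therefore shows
the pipeline can learn a wavelength law of the right shape and magnitude
from data of this size and noise — not that literature performance will
match.

## Evaluation views

- `class_performance`: residuals grouped by substitution class (n, mean
  absolute deviation, max deviation, signed bias). Classes without
  evaluated records are absent, not zero.
- `solvato_trend`: per-molecule predicted vs observed Δλ, the observed
  value taken between the two extreme-ε solvents available; molecules
  measured in fewer than two solvents are skipped with notice. A
  monotonicity flag reports the fraction of consecutive ε-ordered steps
  with nondecreasing predicted λ.
- `tanimoto_distance_matrix`: pairwise 1 − Tanimoto over unique canonical
  structures, exported as labelled CSV for any standard embedding tool
  (e.g. t-SNE); the export, not a picture, is the tested artifact, since
  embedding hyperparameters are not part of this package's claims.

## Numerical and design notes

- `split_dataset` uses `floor(fraction · n)` training rows and accepts any
  split leaving both partitions nonempty (e.g. 4 records at 0.5/0.5).
- Tanimoto of two all-zero fingerprints is 0 by convention; R² of a
  zero-variance target is 0 by convention.
- Model JSON serialization stores weights via `repr`-exact floats, so a
  round trip reproduces predictions bit-for-bit.
- Degenerate inputs raise early with messages: empty graphs, empty solvent
  sets, unsorted ε grids, ε < 1, mismatched fingerprint lengths.
- Unit tests run reduced configurations (256 bits, radius 3, 64 hidden
  units) for speed; the acceptance suite and `scripts/acceptance.py`
  exercise the full 1024-bit / radius-5 / 250-unit configuration on
  ~250-record generated datasets over 5 seeds, the package's standard
  benchmark sizes.

## Known limitations

- The curated literature dataset itself is third-party material and is not
  redistributed; checks against its published statistics require a local
  copy at `data/literature/maleimide_photophysics.csv` (schema in the
  README) and fail plainly without it.
- A single dielectric scalar cannot separate solvents with similar ε but
  different hydrogen-bonding character; predictions for such solvent pairs
  are necessarily close.
- The fingerprint's folded 1024-bit space admits collisions; radius-5
  environments of large substituents may alias.
- No hyperparameter search, deeper architectures, or Gaussian-process
  baselines are provided; exploratory work on this family of models found
  none of them materially better for datasets of this size.
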