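# malphot

Solvent-aware prediction of maleimide absorption and emission maxima.

Maleimides — five-membered ring imides with a substituted alkene — are
compact donor–acceptor fluorophores whose photophysics are tuned by the
heteroatoms on the two alkene carbons (amino → AM, dithio → DTM,
aminothio → ATM, alkoxy) and by the solvent. `malphot` is for chemists and
cheminformaticians who want a fast *first assessment* of a candidate
maleimide's wavelength of maximum absorption (λ_abs) or emission (λ_em)
before committing to synthesis or excited-state quantum chemistry.

The model is a quantitative structure–property regression:

    x = [ ECFP₁₀₂₄(SMILES; radius 5) , ε ]          (1025 inputs)
    λ̂ = w₂ · ReLU(W₁ᵀ x + b₁) + b₂                  (250 hidden units, nm)

a binary extended-connectivity (Morgan) fingerprint of the structure plus
the solvent's dielectric constant ε, fed through a single-hidden-layer
feed-forward network trained by SGD (≤ 2000 epochs, random 90/10
train/test split). Fit quality is the coefficient of determination
R² = 1 − SS_res/SS_tot, reported as the median over reseeded runs. Because
ε enters as an input, a trained model predicts solvatochromic shifts by
simply sweeping ε — e.g. from hexane (1.88) to acetonitrile (37.5).

The package also ships the surrounding tooling: dataset loading and
validation with a solvent→ε registry, per-class error and solvatochromic
trend reports, Tanimoto distance matrices for structure maps, and a
seeded synthetic-data generator with a known ground-truth wavelength law
so the entire pipeline is testable offline. See `docs/methods.md` for the
model and generator details.

## Worked example

```python
from malphot import (GeneratorConfig, ModelConfig, generate_dataset,
                     train_model, solvatochromic_sweep)

records, truth = generate_dataset(GeneratorConfig(n_molecules=64, seed=1))
model, metrics = train_model(records, ModelConfig(target="emission", seed=1))
print(f"R2 train: {metrics.r2_train:.3f}  R2 test: {metrics.r2_test:.3f}")
```

prints

```
R2 train: 0.974  R2 test: 0.868
```

— from 245 simulated records over 64 molecules the network explains ~87 %
of held-out wavelength variance (test MAE 6.3 nm against 5 nm injected
noise). Sweeping the dielectric input for one aminomaleimide
(`examples/03_solvatochromic_sweep.py`):

```
molecule: CN1C(=O)C=C(NC(C)(C)C)C1=O
  eps  1.88  ->   370.2 nm
  eps 37.50  ->   386.2 nm
net shift hexane -> acetonitrile: +15.9 nm
```

a positive (bathochromic) shift of the expected ~15–20 nm magnitude,
learned purely from (structure, solvent, wavelength) triples. The
`examples/` directory has one short script per capability — dataset
generation and summary, training, the sweep above, and per-class error
plus the Tanimoto structure map (where withholding the dithio class from
training inflates its error from 2.1 nm to 26.5 nm, with a −26.5 nm bias).

A thin CLI wraps the same calls:

```sh
malphot simulate --n 64 --seed 1 --out sim
malphot train sim/dataset.csv --target emission --seed 1 --out fit
malphot predict fit/model.json "O=C1NC(=O)C=C1NCC" --solvent hexane
malphot sweep fit/model.json "O=C1NC(=O)C=C1NCC" --eps 1.88 --eps 37.5
malphot evaluate fit/model.json sim/dataset.csv --out reports
malphot summarize sim/dataset.csv
```

## Dataset schema

CSV with header
`smiles,solvent,dielectric,lambda_abs_nm,lambda_em_nm,class,source`;
comma-separated, UTF-8, `.` decimal separator, blank cell = missing.
`dielectric` may be blank when the solvent name resolves in the registry
(`src/malphot/data/solvents.yaml`). Rows without a parsable structure, a
resolvable solvent, or at least one wavelength in [250, 700] nm are
excluded with per-row reasons. Absorption and excitation maxima are
stored as the single `lambda_abs_nm` field.

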