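# vfanose

Signal modeling and discrimination pipeline for measuring volatile fatty
acid (VFA) odors with a nanomechanical sensor array (electronic-nose style).
The package implements, as reusable tested components:

- **`vfanose.kinetics`** — closed-form sensor response under repeated
  injection/purge cycles, built from first-order sorption kinetics
  (diffusion time constant `tau_s`) mixed with viscoelastic stress
  relaxation (`tau_r`, mixing weight `alpha`), in a numerically stable
  time-shifted form that is continuous at every valve switch.  Includes a
  single-cycle receptor-layer concentration model, a carry-over
  (rise/decay symmetry) index, per-cycle peak extraction, and an
  independent ODE/hereditary-integral oracle used to validate the algebra
  and the `alpha <-> E_U/E_R` modulus-ratio mapping.
- **`vfanose.fitting`** — bound-constrained trust-region-reflective least
  squares extracting `(sigma_sat, alpha, tau_s, tau_r, t0)` from response
  curves, with Gauss-Newton standard errors, active-bound reporting, a
  weak-identifiability warning for `tau_r`, and per-cell isolated
  (receptor x analyte) diffusion-time-constant grids.
- **`vfanose.features`** — onset detection (derivative threshold with
  sub-sample refinement, or nominal valve time) and the five
  time-anchored features per channel at offsets `(2, 10, 120, 122, 130)` s
  after onset, baseline-subtracted; feature-matrix assembly and
  replicate-reproducibility summaries.
- **`vfanose.discrimination`** — per-feature z-scoring, deterministic PCA
  (SVD with a fixed sign convention), scree, and silhouette-based cluster
  separation on selected principal components.
- **`vfanose.synthesis`** — a fully synthetic study generator: embedded
  per-sample headspace VFA concentration panels (two silage groups x three
  samples, plus water blanks), receptor x analyte kinetic models for a
  PS / PMMA / Tenax array, additive mixture responses with ideal
  Raoult's-law water suppression, an optional dissociation-induced
  desorption delay for acids in the presence of water, band-limited
  Gaussian noise and linear drift, and both measurement protocols
  (10 s on/off x 4 cycles @ 20 Hz; 2 min sampling / 8 min purge @ 100 Hz).
- **`vfanose.cli`** — end-to-end driver.

## CLI

```sh
# simulate the default synthetic study (21 measurements x 3 channels)
vfanose simulate --out run/data --seed 1

# extract features, run PCA, score group separation
vfanose report --data run/data --out-dir run/analysis

# or individual stages
vfanose features --data run/data --out run/features.csv
vfanose pca --features run/features.csv --out-dir run/pca --plots

# fit a directory of '<receptor>__<analyte>.csv' pure-vapor curves
vfanose fit --curves run/pure --out run/tau_grid.csv --t0 10 -T 10 --n-cycles 4

# everything in one command
vfanose all --out run --seed 1
```

Curve files are plain CSV with `# sampling_rate_hz=...` /
`# channels=...` headers, a `time_s` column and one column per channel.

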