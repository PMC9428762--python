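# heelpad

In-vivo viscoelastic characterisation of the plantar heel pad from
stance-phase gait recordings.

The heel pad — the honeycomb of fat globules and fibroelastic septa
under the calcaneus — is the body's first shock absorber at heel
strike. In diabetes its microstructure degenerates, and the resulting
changes in stiffness, viscosity and energy dissipation are linked to
the risk of plantar ulceration. Measuring those properties *during
actual walking* is possible by synchronizing biplane fluoroscopy
(heel-pad thickness, 50 Hz) with a pressure plate (heel–ground force
and contact area). This package implements the full analysis pipeline
for such recordings, plus a forward simulator so the pipeline can be
validated end to end without any clinical data.

For each step the pipeline builds the stress–strain cycle

- strain ε = (h₀ − thickness)/h₀, with h₀ the thickness at initial
  contact (the *primary thickness*),
- stress σ = force/area (kPa),

splits it into loading and unloading branches, and derives six
properties per heel: h₀, peak strain, peak stress, the Young's modulus
E and viscous modulus η of a modified Kelvin–Voigt model

    σ = E·ε + η·ε·ε̇

fitted by least squares, and the energy dissipation ratio
EDR = (hysteresis-loop area)/(area under loading branch) × 100%.
A normality-routed statistical layer (Shapiro–Wilk and Bartlett
diagnostics selecting Student/Welch/rank-sum, paired t/signed-rank,
ANOVA/Brown–Forsythe/Kruskal–Wallis with SNK-q/Tamhane-T2/Dunn post
hoc, Pearson correlation matrices) reproduces the comparison framework
used for such cohorts. See `docs/methods.md` for the model, the
simulator design and all conventions.

## Worked example

Simulate one step of a heel pad with known parameters and recover them
from the recorded channels alone (`examples/01_simulate_and_fit.py`):

```python
from heelpad import GaitParams, KVParams, extract_properties, simulate_stance

truth = KVParams(E=265.5, eta=66.59, h0=14.85)   # kPa, kPa*s, mm
gait = GaitParams(noise_sd_thickness=0.1, noise_sd_force=2.0, seed=42)
props = extract_properties(simulate_stance(truth, gait))
```

which prints

```
true parameters:   E=265.5 kPa  eta=66.59 kPa*s  h0=14.85 mm
fitted parameters: E=274.4 kPa  eta=68.69 kPa*s  h0=14.54 mm
peak strain 51.3 %   peak stress 127.6 kPa   EDR 59.8 %
fit residual RMS 5.35 kPa
```

The moduli come back within a few per cent of the generating values
despite realistic measurement noise (0.1 mm on thickness, 2 N on
force), and the peak stress lands at the ~140 kPa scale typical of a
healthy heel. Noise-free recordings recover E, η and h₀ to better than
1% across the physiological parameter range.

The other examples build full synthetic cohorts: `02` reproduces the
two-group summary-table comparison (the diabetic pad shows up thinner
and less viscous), `03` the paired loading-history analysis, `04` the
three-group disease-course subgroup analysis with post-hoc pairs, and
`05` the annotated correlation matrices.

A thin CLI wraps the same calls:

```bash
heelpad simulate --seed 7 --out cohort/          # recordings + manifest
heelpad fit --manifest cohort/manifest.csv --out props.csv
heelpad compare --properties props.csv --out comparisons.csv
heelpad report --seed 7 --out bundle/            # all of the above
```

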