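# visnorm

Image-computable encoding models of the fMRI BOLD response in human visual
cortex (V1–V3) to band-pass textures.

A striking observation in human visual cortex is that curved band-pass
contours ("snakes") evoke roughly **twice** the BOLD response of straight,
parallel contours ("gratings") with the same total contrast energy. The
classical normalized-energy model of V1 cannot produce this difference: its
normalization pool weights all orientations equally, so only the *amount*
of contrast energy matters, not how it is distributed across orientation.
`visnorm` implements and compares four models that differ only in their
spatial-pooling stage:

| model | pooling stage | free parameters |
|-------|---------------|-----------------|
| `ce`  | contrast energy: s = mean E(x, y, θ) | g, α |
| `dn`  | untuned divisive normalization: E/(σ + Z), Z a Gaussian pool over all orientations | g, α, σ |
| `otn` | orientation-tuned normalization: the Gaussian surround pools only the same orientation; other orientations act at the center pixel | g, α, σ |
| `noa` | normalization by orientation anisotropy: s = mean(e²)/(σ² + V), V the spread of energy across the 8 orientation channels | g, α, σ |

All four share the same first stage — oriented contrast energy from a bank
of 128 quadrature Gabor filters (8 orientations × 8 spatial frequencies ×
2 phases), E(x,y,θ) = Σ_{φ,f} (I ∗ F_{θ,f,φ})², downsampled to 12 px/deg —
and the same output stage, a compressive power law r = g·s^α predicting
percent signal change. The two orientation-sensitive models (`otn`, `noa`)
reproduce the snake/grating dissociation; the two orientation-blind models
(`ce`, `dn`) cannot. See `docs/methods.md` for the full model equations and
numerical choices.

The package also provides the stimulus synthesizer (snakes, gratings,
waves, noise bars, plaids, circular patterns — all band-pass textures
centered at 3 cycles/deg), a multi-start least-squares fitting engine with
leave-one-out cross-validation, an adapter for the published per-ROI GLM
beta arrays, and the diagnostic experiments (snakes/gratings ratio,
center–surround suppression simulation, synthetic parameter recovery).

## Worked example

Predict the snakes/gratings response ratio for each model on an
energy-matched synthetic battery:

```python
from visnorm import build_filterbank, DIALECTS
from visnorm import experiments as ex

dialect = DIALECTS["small"]            # 6 deg canvas at 24 px/deg
bank = build_filterbank(dialect.ppd)
sets, labels, match = ex.target_battery(dialect, n_exemplars=3, seed=0,
                                        bank=bank)
energies = ex.battery_energies(sets, bank)
reports = ex.run_ratio_experiment(["ce", "dn", "otn", "noa"],
                                  energies, labels)
print(f"energy match (grating/snake): {match:.3f}")
for name, r in reports.items():
    print(f"{name:4s} snake/grating ratio = {r.ratio:.2f}")
```

Output:

```
energy match (grating/snake): 1.000
ce   snake/grating ratio = 1.00
dn   snake/grating ratio = 1.06
otn  snake/grating ratio = 2.18
noa  snake/grating ratio = 4.31
```

The stimulus generator has matched the two classes in total contrast energy
(ratio 1.000), so the contrast-energy model necessarily predicts equal
responses (1.00), and untuned normalization barely separates them (1.06).
The two orientation-sensitive models predict a much larger response to the
curved patterns — the tuned-surround model by a factor ~2, matching the
magnitude observed in cortex.

A command-line interface exposes the same pipeline
(`visnorm synth|fit|cv|ratio|simulate-surround|report <config.yaml>`).

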