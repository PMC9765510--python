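# svquench

Stern-Volmer quenching analysis for plate-reader serial-dilution assays of
phosphorescent O₂ sensors.

Optical O₂ measurement relies on dyes (ruthenium polypyridyl complexes,
Pt-porphyrin nanosensors) whose phosphorescence is quenched by molecular
oxygen — but redox-active metabolites that bacteria secrete (phenazines such
as pyocyanin, flavins, …) quench the same dyes, confounding O₂ readouts in
and around growing cultures. `svquench` is for microbiologists and analytical
chemists who need to screen whether a culture supernatant or a pure compound
quenches their sensor, and how strongly: it turns raw two-phase plate-reader
readings into a fitted quenching constant with a calibrated confidence
interval and a quencher / non-quencher call.

## The model

Quenching follows the linear Stern-Volmer relation

```
I₀ / I = 1 + K_SV [Q]
```

where I₀ is the unquenched sensor intensity, I the intensity at quencher
concentration [Q], and K_SV the Stern-Volmer constant — in M⁻¹ for pure
chemicals, or an effective K̃_SV in (fold dilutions)⁻¹ for supernatants
(neat supernatant ≡ [Q] = 1; K̃_SV = 1 means a neat supernatant halves the
signal). The pipeline:

1. reads each well before ("pre") and after ("post") sensor addition, and
   corrects for the dilution f = v₀/(v₀+v_add) that sensor addition causes:
   I = (post − blank_post) − f·(pre − blank_pre), [Q] = f·[Q_pre] — this
   cancels media background and the sample's own fluorescence exactly;
2. propagates measurement uncertainty through blanking and the I₀/I ratio
   (delta method, with the shared I₀ error handled as a common-mode term);
3. fits (I₀/I − 1) = K_SV·[Q] through the origin by variance-weighted least
   squares — only the slope is fitted, the intercept is pinned at the
   theoretical 1 — and reports a symmetric 95% CI;
4. excludes the top concentration of intrinsically fluorescent compounds
   (inner-filter effect) and calls a sample a **non-quencher** when the
   I₀/I-vs-[Q] correlation is weak (Pearson R < 0.4) or the projected
   quenching at the reference concentration sits within the unquenched
   sensor's own variability.

A seeded synthetic plate generator with the assay's statistical structure
(2-fold series, duplicate × duplicate wells, 3% multiplicative read noise)
validates the whole chain end to end, and a lifetime module fits
mono-exponential phosphorescence decays and the analogous τ₀/τ = 1 + K_SV[Q]
relation. See `docs/methods.md` for the full statistical treatment.

## Worked example

Simulate a plate with a known constant and analyze it back:

```
$ svquench simulate --seed 7 --ksv 1.0 --out plate.csv
INFO svquench: wrote simulated plate (seed=7, K_SV=1) to plate.csv
$ svquench fit plate.csv --out-dir out
INFO svquench: plate.csv: K_SV=1.012 [per_fold_dilution] quencher
INFO svquench: wrote 1 result row(s) to out/results.csv
$ cat out/results.csv
quencher,sensor,unit,k_sv,stderr,ci_low,ci_high,pearson_r,n_included,n_excluded,classification,exclusion_reasons
synthetic quencher,synthetic sensor,per_fold_dilution,1.01241,0.0443611,0.920647,1.10418,0.995912,24,0,quencher,
```

The fitted effective constant is K̃_SV = 1.012 (fold dilutions)⁻¹ with 95% CI
[0.921, 1.104] — covering the generating value 1.0 — from 24 sample wells
with none excluded; I₀/I correlates with concentration at R = 0.996, and the
projected 50% quenching of a neat supernatant far exceeds sensor variability,
so the sample is called a quencher. `out/plate.points.csv` holds the
underlying Stern-Volmer points (q, I₀/I, variance, weight, exclusions) for
plotting. The same `fit` subcommand runs on real exported plate data in the
long CSV format documented in `svquench/io.py`; the library API
(`svquench.analyze_plate`, `svquench.fit_ksv`, `svquench.lifetime_sv`, …)
exposes every stage separately.

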