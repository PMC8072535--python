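# swayemd

Feature screening for quiet-standing force-plate recordings, built around
empirical mode decomposition (EMD) and entropy statistics.

## The problem

Balance assessments for older adults record a subject standing still on a
force plate for 60 s at 100 Hz, giving three ground-reaction forces (Fx,
Fy, Fz) and the center-of-pressure excursions in the anteroposterior
(COPx) and mediolateral (COPy) directions. Summary statistics of the raw
sway signals discriminate poorly between people with and without a falling
history; the discriminative structure lives in individual frequency bands.

`swayemd` implements the band-resolved screening approach:

1. **Decompose** each of the five channels into intrinsic mode functions
   (IMFs) by envelope sifting. Sifting subtracts the mean of the
   cubic-spline envelopes through the local extrema, `d(t) = x(t) − m(t)`,
   until `d` oscillates about zero; that IMF is peeled off and the process
   repeats on the remainder until it is monotonic or the depth cap (7) is
   reached. EMD acts as an adaptive, signal-driven filter bank: IMF1 is
   the fastest mode, IMF7 the slowest.
2. **Extract** five features per series — mean(|x|), sample SD, CV =
   SD/mean(|x|), approximate entropy and sample entropy — on the raw
   series and every IMF: 5 channels × 8 series × 5 features = **200
   features per subject**, named `channel_level_feature` (level 0 = raw),
   e.g. `COPx_4_sample entropy`.
   ApEn = Φ^m − Φ^(m+1) (Pincus; self-matches included); SampEn =
   −ln(A/B) (Richman–Moorman; self-matches excluded); both use Chebyshev
   distance with m = 2 and tolerance r = 0.2 × SD of the analyzed series.
   Lower entropy = more regular, more predictable sway.
3. **Screen** every feature with a two-sample Welch t-test, fall vs
   non-fall, at α = 0.05 (no multiplicity correction by default,
   Benjamini–Hochberg optional).

A seeded synthetic-cohort generator (band-limited oscillators with phase
jitter on 1/f noise, with controllable group contrasts in mid-band
regularity and slow-band amplitude) makes the full pipeline testable and
reproducible without any data download.

## Worked example

```python
from swayemd import (SyntheticCohortSpec, generate_trial,
                     decompose_recording, extract_features)

spec = SyntheticCohortSpec(duration=20.0, seed=42)
rec = generate_trial(spec, "fall", 0)
imfsets = decompose_recording(rec)          # 5 channels -> IMFs + residue
records = extract_features(rec, imfsets)    # 200 named features
values = {r.name: r.value for r in records}
print(values["COPx_0_sample entropy"], values["COPx_4_sample entropy"])
```

prints (for this seed)

```
1.0314  0.3199
```

i.e. the raw anteroposterior sway of this subject has sample entropy
≈ 1.03 while its mid-band component (IMF4, ~1 Hz) has ≈ 0.32 — the mid
band is far more regular than the broadband signal, and it is on this
band-resolved scale that fall/non-fall contrasts emerge. Running the
screening on a default cohort (27 fallers, 49 non-fallers) flags COPx
mid-IMF entropies as *lower* in the fall group (more regular
anteroposterior sway) and slow-band COPy/Fz amplitude features as higher.

The same stages are scriptable from the shell:

```sh
swayemd simulate --seed 5 --out cohort/
swayemd run cohort/[FN]*.csv --metadata cohort/metadata.csv --out results/
```

`examples/` contains one short narrative script per capability
(decomposition, feature extraction, group screening, end-to-end run).

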