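# facespace

Analysis pipeline for face-detection-task (FDT) studies of **face-space
expansion and adaptability**: does the detection advantage for typical
over distinctive (caricatured) faces — and its change with repeated
exposure — scale with a person's face-identity-processing ability?

The package is written for researchers in face-perception individual
differences. It covers the full chain from trial-level go/no-go data to
the confirmatory statistics, plus a synthetic-data generator with known
ground truth so every stage is verifiable by construction:

1. **Simulation** — go/no-go trial streams (480 upright-face go trials
   from 12 identities x 40 occurrences, 48 inverted faces and 48 chairs
   as no-go trials, 11 blocks), exponential within-identity RT learning,
   a constant typicality offset, near-ceiling hit rates with high
   false-alarm rates, and a correlated four-test ability battery.
2. **Preprocessing** — RT exclusion rules (floor at 200 ms, then a
   per-participant ±2 SD pass), signal detection indices (d′, criterion,
   with 1/(2N) extreme-rate correction), and a speed–accuracy check.
3. **Learning rates** — per-presentation rates from the exponential
   learning model (below).
4. **Battery scores** — the mean-rank composite of CFMT+, YBT, GFMT2-S
   and J-BFFT scores (midranks for ties; missing tests ranked on the
   remaining population).
5. **Inference** — paired typicality contrast with paired Cohen's *d*,
   linear mixed models with participant random intercepts and (where
   convergent) random typicality slopes, Satterthwaite *t*-tests,
   BIC model comparison, BIC-approximated Bayes factors, Wilcoxon
   rank-sum gender comparisons and battery inter-correlations.

## The model

Detection RTs for a repeatedly shown identity approach a fixed
asymptote RT<sub>∞</sub> (200 ms, the minimum meaningful RT):

    RT_n = RT_∞ − (RT_∞ − RT_0) · e^(−α·n)

where RT<sub>0</sub> is the RT at the first (retained) presentation and
*n* the occurrence index. Inverting gives the per-presentation learning
rate analysed downstream:

    α = − log( (RT_∞ − RT_n) / (RT_∞ − RT_0) ) / n

Larger α = more efficient learning; α < 0 marks a slowdown;
presentations at or below the asymptote have undefined α and are
excluded with an audit entry.

The confirmatory question is the **typicality × ability interaction**:
in mixed models of RTs (face-space *expansion*) and of learning rates
(face-space *adaptability*), does the typicality effect vary with the
mean-rank ability composite? Evidence for/against the interaction is a
BIC-approximated Bayes factor, BF₁₀ = exp((BIC_null − BIC_alt)/2).

## Worked example

```python
import warnings
from facespace import (SimulationConfig, simulate_dataset, filter_rts,
                       aggregate_score, typicality_contrast, fit_rt_model)

cfg = SimulationConfig(seed=1)          # 52 participants, 576 trials each
data = simulate_dataset(cfg)

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    cleaned = filter_rts(data.trials)
    contrast = typicality_contrast(cleaned)
    comp = aggregate_score(data.battery).table.merge(
        data.battery[["participant_id", "gender"]], on="participant_id")
    model = fit_rt_model(cleaned, comp)

print(f"typicality advantage: {contrast.mean_diff_ms:.2f} ms "
      f"(t({contrast.df}) = {contrast.t:.3f}, p = {contrast.p:.4f}, "
      f"d = {contrast.cohens_d:.2f} [{contrast.d_ci_low:.2f}, {contrast.d_ci_high:.2f}])")
row = model.fit.coef("distinctive:score")
print(f"typicality x ability: beta = {row['estimate']:.3f} ms/rank, "
      f"t({row['df']:.1f}) = {row['t']:.3f}, p = {row['p']:.3f}, "
      f"BF10 = {model.bf10:.3f}")
```

prints

```
typicality advantage: 2.79 ms (t(51) = 4.093, p = 0.0002, d = 0.57 [0.27, 0.86])
typicality x ability: beta = -0.078 ms/rank, t(6925.5) = -1.208, p = 0.227, BF10 = 0.014
```

The generator's default typicality offset is 3 ms, and the paired
contrast recovers it (2.79 ms, reliably non-zero). The generator's
ability coupling is 0, and accordingly the typicality × ability
interaction is non-significant with a Bayes factor far below 1 —
evidence for the *absence* of the coupling.

## Command line

```bash
facespace simulate --seed 1 --out sim/              # trials + battery + truth
facespace preprocess --trials sim/trials.csv --out pre/
facespace learning-rates --trials pre/cleaned_trials.csv --out rates.csv
facespace composite --battery sim/battery.csv --out composite.csv
facespace run-all --seed 1 --out run/               # full report bundle
```

`run-all` writes a deterministic bundle (cleaned trials and audits, SDT
table, learning-rate table, composites, model reports as JSON, recovery
diagnostics against the simulation ground truth), every JSON stamped
with the run-config hash.

## Layout

- `facespace.simulate` — synthetic FDT + battery generator
- `facespace.preprocess` — exclusion rules, SDT, speed–accuracy check
- `facespace.learning` — learning-rate inversion and table
- `facespace.battery` — mean-rank composite, J-BFFT scoring
- `facespace.mixed` — mixed models with Satterthwaite *t*-tests
- `facespace.inference` — contrasts, Bayes factors, rank tests
- `facespace.pipeline` / `facespace.cli` — orchestration and CLI

See `docs/methods.md` for the modelling assumptions, parameter
defaults, and known limitations.
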