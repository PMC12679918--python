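# strigamet

Analysis toolkit for multi-environment maize hybrid trials run under
contrasting *Striga hermonthica* regimes, written for maize breeders and
biometricians screening hybrids for *Striga* tolerance/resistance.

*Striga* (witchweed) is a parasitic plant that can wipe out maize yields in
sub-Saharan Africa. Screening trials evaluate the same hybrids in
artificially infested and *Striga*-free fields, laid out as resolvable
incomplete-block (alpha-lattice) designs, and select on stress-specific
indices rather than yield alone. `strigamet` implements the full analysis
chain:

- **simdata** — a synthetic trial generator with explicit ground truth
  (variance components, per-hybrid latent susceptibility, damage-driven
  yield penalty), so every estimator can be checked for parameter recovery;
- **traits** — trait registry (scales, orientations, log transforms),
  record validation, and derived traits (anthesis–silking interval, grain
  yield from cob field weight at 80 % shelling / 15 % moisture, stand
  density);
- **anova** — combined alpha-lattice ANOVA
  `y = mu + E + Rep(E) + Block(ExRep) + Hybrid + HybridxE + error` with
  sequential SS, mixed-model F denominators (Hybrid tested against
  Hybrid×E), least-square entry means, and the 5 % LSD;
- **indices** — the *Striga* base index on standardized LS means,
  `2·MGY + EPP − (SHD1 + SHD2) − ½·(SEC1 + SEC2)` (positive = tolerant/
  resistant), and the rank summation index (RSI) for *Striga*-free
  selection (lowest total rank = best);
- **assoc** — Pearson correlation tables, cross-regime prediction
  regressions (does *Striga*-free performance predict infested
  performance?), and SAS-style forward stepwise regression with partial R²;
- **gge** — GGE biplot engine: environment-centered SVD of the genotype ×
  environment yield-mean matrix, singular-value partitioning, and the
  "mean versus stability" view with average-environment-axis (AEA)
  projections;
- **cli / pipeline** — `strigamet simulate | analyze | report`, writing all
  report tables as commented CSVs plus a JSON manifest that reproduces the
  run exactly.

See `docs/methods.md` for the statistical details and design choices.

## Worked example

Simulate a default trial (156 entries: 150 hybrids + 6 checks; 4 infested +
3 free environments; 2 replicates in a 12 × 13 lattice = 2184 plots), run
the combined ANOVA for grain yield, and rank hybrids by the base index:

```python
from strigamet import simdata, anova, indices

design = simdata.TrialDesign(seed=1)
truth = simdata.GroundTruth.default(design.n_entries, seed=1)
records = simdata.simulate_trial(design, truth)

tab = anova.combined_anova(records, "YIELD")
print(tab[["source", "df", "mean_sq", "f_value", "p_value"]].round(4).to_string(index=False))

inf = records[records.treatment == "infested"]
means = inf.groupby("entry")[["YIELD", "EPP", "SHD1", "SHD2", "SEC1", "SEC2"]].mean()
base = indices.striga_base_index(means)
print(base[["striga_base_index", "tolerance_class"]].head(3).round(2).to_string())
```

prints

```
      source  df  mean_sq  f_value  p_value
 Environment   6 331.7294 215.5086      0.0
      Rep(E)   7   1.5393   6.3478      0.0
Block(ExRep) 168   0.5209   2.1481      0.0
      Hybrid 155   1.2239   2.9575      0.0
    HybridxE 930   0.4138   1.7066      0.0
       Error 917   0.2425      NaN      NaN
       striga_base_index     tolerance_class
entry
H059               10.60  tolerant/resistant
H023               10.22  tolerant/resistant
H094                8.85  tolerant/resistant
```

The df column is pure design arithmetic (155 hybrid df; 155 × 6 = 930
interaction df; 917 residual df). The Hybrid F of 2.96 against the
Hybrid × E mean square says hybrids differ genuinely in yield across
environments; H059's base index of 10.60 marks it as the most
tolerant/resistant entry of this simulated trial (positive index =
tolerant/resistant, negative = susceptible).

The same analysis end-to-end from a shell, including correlation, stepwise
and GGE outputs:

```sh
strigamet analyze --outdir out --seed 1
strigamet report out
```

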