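# rewardmap

Analysis pipeline for studying how drugs of abuse engage nucleus-accumbens
(NAc) reward ensembles. It reimplements, as a tested Python package, four
computational layers that link brain-wide activity mapping to single-neuron
dynamics:

1. **Whole-brain FOS statistics** — region × sample FOS+ count tables are
   z-scored within processing batches, screened per region with a one-way
   ANOVA across conditions (p < 0.05, k-means phenotyping of the survivors),
   contrasted per drug against saline (Welch t, shared/specific classes), and
   compared across exposure phases by Euclidean distance of saline-subtracted
   profiles.
2. **FOS-Seq** — a gene–activity correlation screen: the saline-subtracted
   FOS contrast and each gene's ISH expression vector are sigmoid transformed
   (logistic of standardized values), Pearson-correlated across matched brain
   regions, calibrated against a Gaussian null fitted to the screen-wide r
   distribution (threshold ±1σ, overridable to the fixed ±0.15), and
   classified with Benjamini–Hochberg FDR at 5%.
3. **Calcium-trace preprocessing** — z = (Fraw − μ)/σ against a 30-s
   pre-presentation baseline; zero-phase 2nd-order Butterworth filtering
   (cut-on 0.266 × Nyquist) with below-median pooled baseline statistics for
   consumption trials; Fcorr = (F − μ)/μ per 1-min segment with μ the
   lowest-quintile mean for drug sessions; 3σ peak detection with a 1.3-s
   (GCaMP6s decay) minimum spacing; activation calls per stimulus (mean
   response > 3σ after consumption start; any supra-3σ peak in the 20–40 min
   cocaine / 30–50 min morphine post-injection window); preference strength
   (Peak_drug − Peak_nat)/(Peak_drug + Peak_nat).
4. **Ensemble dynamics** — motor/nonmotor classification by lagged PCC with
   binarized locomotion (±1..10 frames, adaptive |PCC| threshold in
   0.2–0.4); a connectivity index (pairs with r > 0.3 per segment, normalized
   to the pre-injection baseline); k-means consumption states with NMF/t-SNE
   embeddings; Fisher-exact activation contrasts and top-3-PC variance
   ratios; and tensor component analysis — nonnegative CP decomposition of
   trial × neuron × time tensors — with trial-factor trend regression and a
   state-1-vs-2 neuron contrast.

A first-class synthetic-data module generates every input with planted ground
truth (batch-structured Poisson FOS counts, ISH vectors with planted
correlations, GCaMP6s-like sessions at 4.82 Hz with reward-, movement-locked
and silent populations, multi-session tensors with an amplifying
subpopulation), so every stage is testable end to end without downloads.

## Worked example

```python
import numpy as np
import rewardmap as rm

# 1) simulate a brain-wide FOS experiment with planted cocaine/morphine regions
table, truth = rm.gen_fos_dataset(rm.FosSimSpec(
    n_regions=100,
    responsive_regions={"cocaine": list(range(10)), "morphine": list(range(5, 15))},
    seed=0,
))
z = rm.zscore_by_batch(table)
retained, _ = rm.significant_region_clusters(z, alpha=0.05, k=3, seed=0)
print(f"{len(retained)} of 100 regions pass the ANOVA screen")

vectors, classes = rm.drug_contrast(z)
print(f"{sum(c == 'common' for c in classes.values())} regions respond to both drugs")

# 2) FOS-Seq: screen a synthetic ISH atlas against the cocaine contrast
atlas, gene_truth = rm.gen_ish_atlas(
    rm.IshSimSpec(n_genes=1000, frac_positive=0.05, frac_negative=0.05,
                  signal_r=0.6, seed=1),
    vectors["cocaine"],
)
records, null = rm.fosseq_screen(vectors["cocaine"], atlas)
print(f"null fit: mu={null.mu:.3f}, sigma={null.sigma:.3f} "
      f"-> threshold +/-{null.threshold:.2f}")

# 3) TCA on a 5-session tensor with an amplifying subpopulation (gain 1.5)
X, sessions, _ = rm.gen_multisession_tensor(
    rm.CalciumSimSpec(seed=2, n_neurons=45, populations={"silent": (45, 0.0)}),
    gain_per_session=1.5, n_sessions=5,
)
res = rm.tca_fit(X, rank=2, restarts=5, seed=0)
trend = rm.tca_trend_and_contrast(res, sessions, X)
j = int(np.argmax(np.abs(trend.slopes)))
print(f"state {j + 1} trial factor grows with slope {trend.slopes[j]:.2f} "
      f"(p = {trend.slope_pvalues[j]:.1e})")
```

Output:

```
17 of 100 regions pass the ANOVA screen
5 regions respond to both drugs
null fit: mu=0.001, sigma=0.212 -> threshold +/-0.21
state 1 trial factor grows with slope 2.89 (p = 2.7e-08)
```

The screen retains the planted responsive regions plus the expected ~5%
type-I background; the five regions planted in both drug conditions come out
"common"; the null σ exceeds the pure-null 1/√99 ≈ 0.10 because 10% of genes
carry planted signal (the 1σ threshold adapts accordingly); and the planted
amplifying component produces a strongly positive trial-factor trend.

The same analyses are available from the shell:

```sh
rewardmap simulate --kind fos --seed 0 --out sim/
rewardmap fosmap --table sim/region_table.csv --out maps/
rewardmap run --config config.yaml --out results/
```

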