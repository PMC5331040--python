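# rootmix

Root samples washed out of field soil cores are never pure: alongside the
current crop's roots they contain **extraneous organic matter (EOM)** — dead
roots of preceding crops and weeds, incorporated residues, manure remnants.
Ignoring EOM inflates root-biomass estimates. When the crop is a C4 plant
(maize, δ¹³C ≈ −13‰) grown after years of C3 vegetation (δ¹³C ≈ −29‰), the
carbon isotope ratio of a sample reveals how much of its carbon is really
recent crop root.

`rootmix` implements that partitioning as a tested pipeline for
isotope-ecology and plant–soil researchers:

* **Two-pool mixing model.** For each sample,
  `f_RBC = (δ¹³C_s − δ¹³C_EOM) / (δ¹³C_RB − δ¹³C_EOM)`,
  the C-mass fraction of recent root biomass C; `f_RBC` and the EOM-C
  fraction sum to 1. Raw values outside [0, 1] are clamped with an audit
  flag.
* **Endmember estimation from study data.** The root signature `δ¹³C_RB` is
  the mean of coarse-root values strictly above the empirical 0.8 quantile
  (the least-contaminated tail, treated as pure root); `δ¹³C_EOM` is the
  mean of a prior-year ley fine-root reference set. A permutation check
  warns if candidate values differ between treatments or depths before
  pooling.
* **Uncertainty.** First-order (delta-method) SE over the three variance
  sources (instrument, root endmember, EOM endmember) and a per-sample
  Monte-Carlo CI with clamping.
* **Size-class pooling.** Mass-weighted (optionally C-mass-weighted)
  averaging of coarse and fine fractions into pooled records.
* **Factorial summaries and permutation tests** that respect the split-plot
  design: treatment permuted across whole plots, depth within plots,
  position/size class/exclusion within plot × depth cells; interactions via
  Freedman–Lane residual permutation.
* **Synthetic-study generator** emulating the 3 treatments × 4 blocks ×
  3 depths × 2 coring streams design (144 planned records, 5 missing), with
  logit-normal latent fractions, so the whole pipeline is testable against
  a known truth.

## Worked example

Simulate a study, estimate endmembers, partition every sample, and test the
design factors:

```bash
rootmix simulate --out-dir study --seed 7
rootmix endmembers --samples study/samples.csv --reference study/reference.csv --out endmembers.csv
rootmix mix --samples study/samples.csv --reference study/reference.csv --out fractions.csv --mc-draws 0 --seed 7
rootmix summarize --fractions fractions.csv --factors depth,treatment \
    --tests depth,position,size_class,eom_excluded,depth:position --b 1999 --seed 7 --out summary.csv
```

which prints

```
root: -13.39 ± 0.54 per mil (n=7)
eom:  -29.06 ± 0.28 per mil (n=12)
wrote 174 results to fractions.csv
depth: statistic=0.14830 p=0.0310 (B=1999)
position: statistic=0.75315 p=0.0005 (B=1999)
size_class: statistic=2.44534 p=0.0005 (B=1999)
eom_excluded: statistic=0.58956 p=0.0010 (B=1999)
depth:position: statistic=0.00394 p=0.9240 (B=1999)
```

The root endmember is recovered from the coarse-root upper tail (7 of 36
values selected); 174 results are 139 measured samples plus 35 synthesized
pooled Puerckhauer records. The permutation p-values say depth, sampling
position, root size class and EOM exclusion all shift the recent-root C
fraction in this realization. The depth × treatment table of group means:

```
Depth [m]  BIOORG1           BIOORG2           CONFYM2
0-0.25     0.52 ± 0.08 (15)  0.53 ± 0.07 (14)  0.52 ± 0.05 (16)
0.25-0.5   0.56 ± 0.07 (16)  0.66 ± 0.05 (16)  0.64 ± 0.06 (15)
0.5-0.75   0.59 ± 0.07 (16)  0.61 ± 0.06 (16)  0.67 ± 0.06 (15)
```

Each cell is "mean ± SE (n)" of the recent-root C fraction; the overall
mean here is 0.589, i.e. ~41% of the recovered root C is EOM.

The same pipeline is available as a library:

```python
import rootmix as rm

table, reference, truth = rm.generate_study(rm.Scenario(), seed=7)
analysis = rm.analyze_study(table, reference)
print(analysis.pair.root.mean, analysis.pair.root.n)
print(rm.report_table2(rm.subset_frame(analysis.frame, "full")))
```

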