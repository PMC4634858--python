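# tmtflow

Proteogenomic data integration for isobaric-label (TMT) experiments:
peptide-level quality control, rank-invariant reference normalization,
all-possible-protein **Tukey-biweight rollup**, Welch differential testing,
probe-to-protein matching with gene–protein **concordance**, and
cross-study comparison of proteomic inventories — plus a synthetic-data
generator that emulates 6-plex TMT peptide tables and matched microarray
data with full ground truth, so every stage of the pipeline can be
verified by recovery experiments without any external download.

The package is aimed at computational proteomics practitioners comparing
tumor histologies (the canonical design is 3 lung adenocarcinoma vs 3
squamous cell carcinoma samples on TMT channels 126–131) and at method
developers who need a reproducible, fully-specified reference pipeline
for reporter-ion quantification.

## The method

Starting from a MaxQuant-style peptide table (one row per peptide
sequence, one reporter-intensity column per channel):

1. **Filter** peptides with posterior error probability PEP > 0.1,
   reversed (decoy) sequences, contaminants, and rows with more missing
   reporter intensities than the larger of the two group sizes
   (for 3 vs 3: more than 3 of 6).
2. **Log2-transform** and **normalize** each sample onto a reference
   (the sample whose mean is closest to the median of sample means) with
   a single log2 offset estimated by a one-step biweight over an
   iteratively refined rank-invariant feature subset.
3. **Map peptides to all possible proteins** — no razor/Occam
   assignment — and aggregate each protein's peptides per sample with the
   one-step Tukey biweight: with `M` the median and `S` the (unscaled)
   median absolute deviation,

   ```
   u_i = (x_i − M) / (c·S + ε),   c = 5, ε = 1e-4
   w_i = (1 − u_i²)²  if |u_i| < 1  else 0
   protein intensity = Σ w_i x_i / Σ w_i      (median if all w_i = 0)
   ```

   The biweight down-weights outlying peptides, so a protein estimate is
   robust where a plain intensity sum is dragged by aberrant or missing
   peptides (`razor_rollup` ships as a benchmarking comparator).
4. **Test** each protein with a Welch unequal-variance t-test
   (Satterthwaite df); report log2 FC = log2(SCC/ADC) and call
   significance at *P* < 0.05 with linear fold-change > 1.5 or < 1/1.5,
   with no multiple-testing adjustment.
5. **Integrate** with microarray data: choose the probe with the highest
   average intensity per protein, then compute global (pooled) and
   per-pair Pearson/Spearman concordance, differential-call overlap with
   direction agreement, and complete-linkage clustering of samples on
   correlation distance (1 − R).

## Worked example

```python
import tmtflow as tf

params = tf.tmt_like(n_proteins=500, seed=42)     # ~0.1% missingness preset
truth  = tf.generate_ground_truth(params)
table  = tf.simulate_peptide_table(truth)
exprs, mapping = tf.simulate_microarray(truth)

res = tf.run_pipeline(tf.RunConfig(seed=42), truth.design, table, exprs, mapping)
print(res.report["filter"])         # {'input_rows': 3776, ..., 'retained': 3702}
print(res.report["rollup"])         # 500 proteins, 7.40 peptides/protein,
                                    # 95 single-peptide proteins (19%)
print(res.report["differential_proteins"]["called"])   # 57
print(res.report["protein_cluster"]["two_cut_labels"])
# {'ADC1': 2, 'ADC2': 2, 'ADC3': 2, 'SCC1': 1, 'SCC2': 1, 'SCC3': 1}
```

The run filters 74 of 3,776 peptide rows (37 by PEP, 37 contaminants),
quantifies all 500 proteins, and calls 57 differential proteins at
*P* < 0.05 + fold-change — recovering 49 of the 50 proteins simulated
with a true |log2 FC| = 2 (sensitivity 0.98). The two-cluster cut of the
protein matrix separates the ADC and SCC samples exactly. The strongest
calls look like:

```
protein  mean_ADC  mean_SCC  log2fc       t     df      p
P00496     12.828    14.861   2.033  76.965  3.814  0.000
P00232     10.691     8.613  -2.077 -63.084  3.917  0.000
P00055     10.849    12.794   1.945  54.976  3.726  0.000
```

i.e. protein `P00496` is 2^2.03 ≈ 4.1-fold higher in SCC, matching its
simulated effect of +2 log2 units.

The same chain is scriptable from the shell:

```
tmtflow simulate --out-dir sim --seed 42 --n-proteins 500
tmtflow process  --peptides sim/peptides.tsv --design sim/design.tsv \
                 --expression sim/expression.tsv --mapping sim/mapping.tsv \
                 --out-dir results
tmtflow compare  --study A a/peptides.tsv a/design.tsv \
                 --study B b/peptides.tsv b/design.tsv --out compare.json
```

`results/` then holds every intermediate TSV plus a `report.json` with
all stage counts; identical inputs and seed give byte-identical outputs.

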