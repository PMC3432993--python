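# toxsig

Cross-tissue co-expression pattern extraction and blood-based toxicity
signatures, with a synthetic-study generator emulating a two-tissue rat
hepatotoxicity design.

## Scientific problem

Hepatotoxicant exposure changes gene expression in the liver, but liver
biopsies are impractical for routine monitoring. If a set of transcripts
responds *identically* in whole blood and liver — same direction, comparable
magnitude, same dose dependence — then blood expression can act as a
surrogate readout of liver injury. The analysis problem is therefore:

1. From paired liver/blood expression profiles across dose groups, extract
   the dominant co-expression patterns and the genes that follow them.
2. Flag patterns whose liver and blood responses agree (cross-tissue
   co-regulated genes): these form the candidate blood signature.
3. Validate the signature on an independent animal set: do the signature
   genes separate exposed from unexposed animals, and — when some dosed
   animals fail to develop injury — do they track the injury phenotype
   (serum ALT) rather than the administered dose?

`toxsig` implements the pattern-extraction method, the signature evaluation,
and a synthetic data generator whose defaults emulate the motivating study
design (training arm: 4 rats/group at 0/150/1500/2500 mg/kg; test arm:
6 rats/group at 0/150/1500/2000 mg/kg; liver and blood per animal; two
dye-swap arrays per animal × tissue; 6 h and 24 h time points).

## Model

Expression values are log2 treated/control ratios. Columns are grouped by
tissue × dose class (subtoxic, toxic); vehicle animals define the control
pool and are excluded from grouping. For each gene with group means
ḡ₁, …, ḡₘ (group sizes n₁, …, nₘ) and within-group variances σ̂ᵢ²:

- **Signal** S = max(ḡᵢ) if all group means are positive; min(ḡᵢ) if all are
  negative; max(ḡᵢ) − min(ḡᵢ) otherwise.
- **Noise** N = √( σ̂²_pooled · Σᵢ 1/nᵢ ), with σ̂²_pooled the
  degrees-of-freedom-weighted pooled within-group variance.
- **SNR** = S / N. With one group, |SNR| equals the one-sample t statistic;
  with two groups of opposite-sign means it equals the pooled two-sample t.

Pattern extraction is greedy: genes passing magnitude gates (|S| > 0.4 log2,
|SNR| > 3) seed patterns when at least `min_cluster_size` uncovered genes
correlate with the seed at r ≥ r\*, where r\* is the Pearson correlation whose
two-tailed p equals `p_threshold` (0.001) at the design's degrees of freedom
(r\* = t_c / √(t_c² + df), df = n − 2). Highly similar patterns are merged,
genes are reassigned to their best-matching final pattern, and genes are
categorized to a pattern when r ≥ 0.64 and the magnitude gates hold. A
pattern is flagged **cross-tissue co-regulated** when both its liver and
blood sub-profiles exceed the signal gate with the same sign and their
dose-class mean vectors agree (correlation ≥ 0.5).

Signature evaluation projects the per-animal signature-gene matrix with PCA,
clusters animals by average-linkage hierarchical clustering on Euclidean
distance, cuts the tree into two clusters, and scores the best two-cluster
relabeling against either dose labels (unexposed vs exposed) or injury
labels from serum ALT (< 100 U/L uninjured, ≥ 200 U/L injured).

## Worked example

```python
import toxsig as ts

# Training arm, 6 h: six planted pattern templates (200 genes each)
# among 4000 background genes.
data = ts.simulate_study(
    "training", 6,
    templates=ts.default_templates(200),
    n_background_genes=4000, noise_sd=0.1, seed=0,
)
data["expression"].shape          # (5200, 64): genes x dye-swap arrays

result = ts.run_extract(data["expression"], data["metadata"])
result["r_star"]                  # 0.4601  (p = 0.001 at 48 columns)
len(result["patterns"])           # 6
```

Per-pattern summary for seed 0 (members, signal, SNR, co-regulation flag):

| pattern | members | S | SNR | co-regulated |
|---|---|---|---|---|
| 1 | 201 | 2.35 | 628.6 | no (interaction shape) |
| 2 | 200 | 2.39 | 585.0 | no (interaction shape) |
| 3 | 200 | 2.03 | 497.4 | no (opposite tissue directions) |
| 4 | 200 | 2.01 | 508.3 | no (opposite tissue directions) |
| 5 | 202 | −1.59 | −349.7 | yes (down in both tissues) |
| 6 | 203 | 1.57 | 390.7 | yes (up in both tissues) |

1200 of 5200 genes are categorized; the co-regulated signature contains
400 genes (`ts.signature_table(result)`), e.g.:

```
          gene_id  pattern_id direction        r         S        SNR
down_both_dose_g1           5      down 0.964197 -1.404215 -20.279055
down_both_dose_g2           5      down 0.962449 -1.409744 -19.382396
down_both_dose_g3           5      down 0.986653 -1.922793 -31.621019
```

Validating that signature on an independent test arm with one planted
non-responder (a toxic-dose animal that develops no injury):

```python
sig = ts.signature_table(result)["gene_id"].tolist()
test = ts.simulate_study(
    "test", 6, templates=ts.default_templates(200),
    n_background_genes=4000, noise_sd=0.2, seed=1,
    nonresponders=["te6h_d1500_r2"],
)
res = ts.run_classify(test["expression"], test["metadata"], sig, alt=test["alt"])
res["liver"]["dose"]["report"].purity         # 0.9444 (17/18 animals)
res["liver"]["dose"]["report"].misclassified  # ['te6h_d1500_r2']
res["blood"]["injury"]["report"].purity       # 1.0
```

Against dose labels both tissues misclassify exactly the planted
non-responder (purity 17/18 = 0.944); against ALT-derived injury labels the
separation is perfect (purity 1.0) — the signature tracks phenotype, not dose.

The same pipeline is available from the command line:

```bash
toxsig simulate --arm training --time-h 6 --seed 0 --noise-sd 0.1 --out runs/train
toxsig extract  --data runs/train --out runs/train_extract
toxsig simulate --arm test --time-h 6 --seed 1 --out runs/test
toxsig classify --data runs/test --signature runs/train_extract/signature.tsv --out runs/test_classify
toxsig compare  --run-a runs/train_extract --run-b runs/other_extract --out runs/compare
```

Every command echoes its resolved configuration to `run_config.yaml` in the
output directory.

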