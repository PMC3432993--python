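# Methods

## Data model

The unit of analysis is a gene × array matrix of log2 treated/control
expression ratios from a two-tissue rodent dosing study. Each animal
contributes one liver and one whole-blood sample; each sample is hybridized
on two arrays with swapped dye orientation. Dye-swap pairs are combined as
(forward − reverse)/2 after orienting all columns forward, which cancels
gene-specific dye bias and reduces technical variance. An optional
reference-alignment step median-centers each combined column; it is off by
default because simulated data carry no array-level offsets.

Columns are grouped by tissue × dose class. Dose class is derived from the
administered dose: 0 mg/kg is vehicle, doses ≤ 150 mg/kg are subtoxic, and
higher doses are toxic. Vehicle columns are excluded from the group
structure (they define the denominator of the ratios, not a treatment
group). Groups of a single column are rejected unless explicitly allowed,
since they contribute no within-group variance.

## Per-gene statistics

For group means ḡ₁…ḡₘ, group sizes n₁…nₘ and within-group sample variances
σ̂ᵢ² (ddof = 1):

- **Signal** S = max ḡᵢ if all means > 0; min ḡᵢ if all < 0; max − min
  otherwise. S is a signed log2 quantity: its sign encodes direction for
  same-direction profiles, and the mixed case measures dynamic range.
  A `strict_eq1_sign` flag selects an alternative convention that negates S
  in the all-positive case; |S| is unchanged, so every downstream gate
  (which uses |S|) is unaffected. The default convention keeps S positive
  for up-regulated profiles, which is what the co-regulation direction check
  needs.
- **Noise** N = √(σ̂²_pooled · Σᵢ 1/nᵢ), where σ̂²_pooled pools the group
  variances weighted by their degrees of freedom. N has log2-ratio units.
- **SNR** = S/N. With m = 1 the quantity |SNR| is exactly the one-sample
  t statistic; with m = 2 and opposite-sign group means it is exactly the
  pooled two-sample t statistic. Both identities are enforced by tests to
  1e-10. If N = 0 and S ≠ 0 the SNR is ±∞ and the profile is flagged
  degenerate; if both are 0 the SNR is 0.

## Pattern extraction

1. **Eligibility.** Genes must pass |S| > `s_magnitude` and
   |SNR| > `snr_min`. The SNR gate is applied to |SNR| so that strongly
   down-regulated profiles (negative S) are eligible symmetrically.
2. **Seeding.** Eligible genes are ranked by |SNR|. The highest-ranked
   uncovered gene seeds a pattern if at least `min_cluster_size` uncovered
   genes correlate with it at Pearson r ≥ r\*. r\* converts the significance
   level `p_threshold` into a correlation radius via the exact t
   distribution of r under the null: r\* = t_c/√(t_c² + df) with df = n − 2
   and t_c the two-tailed critical value. This keeps the gate's meaning
   fixed as the number of columns changes (r\* ≈ 0.629 at 26 columns,
   ≈ 0.460 at 50).
3. **Merging.** While the two most-correlated pattern representatives
   (member-mean profiles) correlate at r ≥ `merge_r`, they are merged.
   `merge_r` defaults to r\*, i.e. patterns are merged whenever they are not
   statistically distinguishable at `p_threshold`.
4. **Reassignment.** One pass reassigns every covered gene to its
   best-correlated final representative, keeping it only if r ≥ r\*. A
   single pass suffices because representatives are frozen at this point;
   iterating would re-introduce order dependence.
5. **Categorization.** Independently of coverage, every gene is assigned to
   its best-correlated pattern when r ≥ `r_categorize`, |S| > `s_magnitude`
   and |SNR| > `snr_min`. Ties go to the lower pattern id for determinism.

A pattern is **cross-tissue co-regulated** when, computed on its
representative profile, both per-tissue signals exceed `s_magnitude` with
the same sign, and the per-tissue dose-class mean vectors correlate at
r ≥ `agreement_r` (the check is vacuously true if a vector is constant,
since agreement of shape is then undefined but direction and magnitude
already passed).

### Parameter defaults

| parameter | default | units | rationale |
|---|---|---|---|
| `p_threshold` | 0.001 | probability | pattern-seeding significance; sets r\* from the design df |
| `r_categorize` | 0.64 | Pearson r | stricter gate for final gene-to-pattern assignment |
| `s_magnitude` | 0.4 | log2 ratio | ≈ 1.3-fold change; below this, direction is unreliable |
| `snr_min` | 3.0 | unitless (t-scale) | ≈ p < 0.01 at the design's group sizes |
| `min_cluster_size` | 10 | genes | a pattern must be supported by several genes, not one outlier |
| `merge_r` | r\* | Pearson r | merge patterns indistinguishable at `p_threshold` |
| `agreement_r` | 0.5 | Pearson r | dose-response shape agreement across tissues |

## Signature evaluation

The signature matrix is animals × signature genes for one tissue, taken from
dye-swap-corrected data. Evaluation uses two independent views:

- **PCA** (2 components, full SVD) for visualization; component signs are
  fixed by making the largest-|loading| gene positive, so coordinates are
  reproducible across runs and animal orderings.
- **Hierarchical clustering** (average linkage, Euclidean distance), cut
  into two clusters. Purity is the best of the two possible cluster→class
  mappings, i.e. the fraction of animals correctly classified by the
  optimal relabeling. With 18 test-arm animals one misplaced animal gives
  purity 17/18 ≈ 0.944.

Class labels are either **dose** (vehicle+subtoxic vs toxic; vehicle animals
are excluded when ratios are relative to vehicle) or **injury** from serum
ALT: < 100 U/L uninjured, ≥ 200 U/L injured, the gap in between
indeterminate and excluded.

## Synthetic generator

### What it emulates

- The two-arm design: training 4 rats/group at 0/150/1500/2500 mg/kg; test
  6 rats/group at 0/150/1500/2000 mg/kg; 6 h and 24 h; liver and blood per
  animal; two dye-swap arrays per animal × tissue (reverse arrays stored
  sign-flipped).
- Planted co-expression structure: each pattern template specifies a mean
  log2 ratio per tissue × dose-class cell; member genes get a multiplicative
  loading drawn from U(0.7, 1.3) and i.i.d. Gaussian noise (default
  sd = 0.2 log2 units per array). The six default templates are three
  mutually orthogonal contrast directions and their negations — two
  co-regulated (same direction in both tissues, dose-dependent), two
  opposite-direction, two tissue × dose interactions — so extraction must
  both find and *separate* them.
- Background genes: pure noise, no planted structure.
- Serum ALT: uninjured animals draw from a truncated normal
  (mean 62, sd 13, bounds 30–100 U/L); injured animals draw log-uniformly
  from 200–12000 U/L, reflecting the heavy right skew of injury-range ALT.
  Injury occurs only in toxic-dose responders at 24 h (at 6 h, injury has
  not yet developed, while expression already responds).
- Responder heterogeneity: each toxic animal is a responder with probability
  `responder_fraction` (or per an explicit list). Non-responders' expression
  is anchored to the subtoxic response level, decoupling dose from
  phenotype — the mechanism that lets injury labels outperform dose labels.

### What it does not emulate

- Probe-level artifacts: cross-hybridization, saturation, spot defects,
  intensity-dependent (LOWESS-type) dye bias. Dye bias is modeled only as
  orientation sign, which dye-swap averaging removes exactly.
- Correlated noise between genes outside planted patterns, batch effects,
  or animal-level random effects shared across tissues.
- Biological annotation: gene identifiers are synthetic; no pathway
  structure or tissue-specific expression baselines.
- Time as a continuous variable: 6 h and 24 h differ only through the
  injury model, not through distinct expression kinetics.

Consequently, recovery and calibration results on synthetic data bound what
the algorithm does under its own assumptions; they do not predict
performance on array data with structured technical noise.

## Numerical choices

- Row correlations are computed by standardizing rows and taking one matrix
  product; constant rows are flagged invalid rather than producing NaNs.
- Pooled variance uses ddof = 1 per group; singleton groups (when allowed)
  contribute 0 degrees of freedom to the pool but still add 1/nᵢ = 1 to the
  noise sum, so they inflate N rather than silently vanishing.
- Purity over two clusters is computed by exact enumeration of the two
  label mappings, not by a heuristic.
- Signature intersection compares gene sets by identifier and
  cross-tabulates per-run directions (sign of S), reporting intersection,
  union and the direction cross-table.

## Limitations

- The greedy seed-merge-reassign extraction is order-dependent by design
  (|SNR| ranking); gene-order invariance of the *resulting memberships* is
  tested, but pattern numbering is not canonical.
- Thresholds are fixed defaults, not estimated from data; no multiplicity
  correction is applied beyond the implicit stringency of the gates.
- The two-cluster tree cut assumes a binary class structure; designs with
  more than two phenotype classes need a different cut.
- ALT is the only phenotype variable; histopathology grades and other serum
  chemistries present in real studies are out of scope.
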