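# Methods

## Problem and model

The package classifies 41-nt RNA windows centered on a candidate adenosine
as m6Am-modified or not. The model is a fuse-then-select design: nine
sequence encodings are concatenated into one numeric vector per window, a
tree-ensemble importance ranking prunes that vector to a prefix, and a
gradient-boosted decision-tree classifier is trained on the prefix. No
structure, conservation or genomic-context features enter the model — the
sequence window is the only input.

## Sequence windows

Windows are validated on read: fixed length (default 41), alphabet
{A, C, G, U} after normalization (T→U, lowercase uppercased), and — by
default — an adenosine at 1-based position 21. The center check is a
toggle because pre-windowed external data is not always guaranteed to be
A-centered; ambiguity codes are rejected rather than imputed, since no
encoder defines a value for them.

## Encoders

All blocks order their features lexicographically over A<C<G<U; the order
is a package convention required for model reproducibility. For a window of
length L:

| scheme | content | dims (L=41) |
|---|---|---|
| PseEIIP | per-position EIIP value; then EIIP_xyz·f_xyz per trinucleotide, EIIP_xyz the sum of the three base potentials (A 0.1260, C 0.1340, G 0.0806, U 0.1335), f_xyz = N_xyz/(L−2) | L+64 = 105 |
| Hash | each sliding k-mer (k=2) read as a base-4 number with digits A=0, G=1, C=2, U=3 | L−1 = 40 |
| DBE | 4-bit code per overlapping dinucleotide; A=(0,0), C=(1,0), G=(1,1), U=(0,1) — fixed so AA→0000, AU→0001, AC→0010, GG→1111 | 4(L−1) = 160 |
| NCP | per base the (ring, amino/keto, H-bond) triple: A=(1,1,1), C=(0,1,0), G=(1,0,0), U=(0,0,1) | 3L = 123 |
| PseKNC | 4^k normalized k-tuple frequencies plus λ ω-weighted dinucleotide correlation factors; one shared denominator, so the block sums to 1 | 4^k+λ = 20 |
| DNM | per dinucleotide: count n, mean 1-based position u, positional variance D² = Σ(i−u)²/(n(L−1)); (0,0,0) when absent | 48 |
| K-mer | occurrence counts for k ∈ {2,3,4} | 16+64+256 = 336 |
| SCPseTNC | 64 normalized trinucleotide frequencies; with λ>0, one series-correlation factor per (lag, property) pair from products of standardized property values | 64+λΛ = 64 |
| Ksnpf | frequency of ordered base pairs k apart (k=1..5), S/(L−k−1) | 16·5 = 80 |

Correlation factors: PseKNC's tier-j factor averages
Φ = mean over properties of the squared difference of standardized property
values between dinucleotides j steps apart; SCPseTNC's factor for lag m and
property ξ averages the product P_ξ(tri_i)·P_ξ(tri_{i+m}) over
i = 1..L−m−3. SCPseTNC's summation range follows the conventional printed
form, which stops one position short of the last geometrically valid pair;
the factor is a plain mean either way.

### Defaults and open choices

* **PseKNC k=2, λ=4, ω=0.1.** The combined default vector is 976-dimensional.
  The nine schemes admit no single "canonical" total: the seven schemes with
  fixed contracts contribute 892 dims, and the two pseudo-composition schemes
  are configuration-dependent. λ=4 keeps a visible correlation tier while
  staying far below the λ<L−1 bound; ω=0.1 is the customary weak weighting
  of correlation against composition.
* **SCPseTNC λ=0** by default, emitting exactly the 64 frequency components;
  λ>0 (with Λ=12 properties) is available through the config.
* **Property tables** (`physicochem.py`, overridable): six standard RNA
  duplex step-geometry indices (shift/slide/rise/tilt/roll/twist) for
  dinucleotides, and twelve trinucleotide indices constructed
  deterministically — the six step indices averaged over the two overlapping
  steps, summed nearest-neighbour stacking free energy, and five additive
  per-base descriptors (GC, purine, amino counts, EIIP sum, molecular
  weight). No canonical RNA trinucleotide table is in general circulation,
  so the package defines its own reproducible set; because every property is
  standardized to zero mean/unit variance across the 16 or 64 oligos before
  use, only relative profiles matter.
* **DNM absent-dinucleotide convention** (0,0,0) avoids 0/0 in the mean and
  variance.

## Feature selection

Importance comes from an `ExtraTreesClassifier` (default 100 trees,
seeded); ties in importance break stably by feature name. With several
balanced sub-training datasets, per-dataset importances are normalized to
sum 1 and averaged (`rank_features_multi`) so no single negative shard
dominates the ranking.

The equidistant search evaluates ranking prefixes of sizes step, 2·step, …
plus the full set (e.g. 23 evaluations for 1120 features at step 50), scores
each by an injected evaluator (typically mean CV AUC), and keeps the best
size, ties toward the smaller subset. Prefixes are nested by construction.

## Modeling

The classifier is LightGBM gradient boosting with a depth-oriented
parameterization: `iterations` → boosting rounds, `depth` → `max_depth`
with a leaf budget of 2^depth capped at 128, plus `learning_rate`.
Training is single-threaded with `deterministic=True`, so a fixed seed gives
bit-identical predictions, including across a save/load round trip (native
text model + JSON sidecar with feature names, config hash and training ids).
`loss_function` defaults to binary log-loss; a "MultiClass" compatibility
value maps to a 2-class softmax, which ranks identically for binary labels.
Prediction refuses feature matrices whose column names or order differ from
those recorded at training — no silent reordering. Hard labels use a fixed
0.5 threshold.

`grid_search` enumerates the Cartesian product of the grids (the reference
grids are 6 iteration values × depths 1–10 × 6 learning rates = 360 cells)
lazily, scores each by mean stratified-CV AUC, records failures per cell
without aborting, and breaks ties toward fewer iterations, then smaller
depth, then smaller learning rate. The preset `TUNED_CONFIG`
(iterations 2000, depth 9, learning rate 0.03) reflects a full-scale tuning
outcome and is far heavier than needed for desk-scale synthetic runs, which
use ~100 rounds at depth 5.

## Evaluation

`compute_metrics` derives ACC/Sn/Sp/F1/MCC from the confusion table at a
0.5 threshold and AUC from the score ranking; single-class inputs raise
rather than return NaN; an all-zero MCC denominator yields 0. The identity
ACC = (Sn·P + Sp·N)/(P+N) holds for every confusion table and is
brute-force-tested over all tables with P, N ≤ 6. Cross-validation is
stratified k-fold (the near-1:1 sub-training datasets make stratification
nearly equivalent to plain splitting, but it guarantees both classes per
fold), seeded and deterministic. The independent test asserts id-level
disjointness from the training windows recorded in the model bundle.
PR curves set precision to 1 at recall 0.

Aggregation across sub-training datasets reports the mean of the per-dataset
means and their **sample** standard deviation (n−1 denominator) — the SD is
over the 10 dataset-level means, not over the 100 individual folds.

## Synthetic data

The generator emulates the benchmark's shape: 41-nt windows, center A in
both classes, defaults of 3700 positives and 37,000 negatives over a uniform
background. Class signal is planted twice so both positional and
compositional encoder families can see it: a 6-nt PWM (consensus GGCAGC,
0.85 per-position weight) starting two bases downstream of the center, and
a mild C/G composition shift (15% relative at full effect). `effect_size`
interpolates both toward the shared background; at 0 the classes are
identically distributed and any classifier sits at AUC 0.5. The generator
does **not** mimic real m6Am biology (no transcription-start-site context,
no BCA-motif statistics, no redundancy structure), so passing tests
demonstrate that the pipeline machinery recovers plantable signal — not
that real benchmark performance is reproduced. Real-benchmark headline
numbers require the external datasets and are out of scope here.

Desk-scale problem sizes used by the tests: the planted-signal experiment
runs one balanced 3700+3700 dataset with 10-fold CV at 100 boosting rounds;
unit and property tests use hundreds of windows. These sizes were chosen to
make the statistical assertions (AUC > 0.9 at high effect; AUC in
[0.47, 0.53] at null, where the 10-fold mean has SD ≈ 0.007) comfortably
stable under the fixed seeds.

## Known limitations

* The trinucleotide property defaults are package-defined, not a published
  table; override `scptnc_properties` to use a specific source.
* CD-HIT redundancy reduction is an upstream step; `cdhit_reduce` only
  shells out to an installed `cd-hit-est` and raises when absent.
* The boosting backend is LightGBM; CatBoost-specific options
  (`leaf_estimation_method`, `bootstrap_type`, ordered target statistics for
  categorical features) are recorded for provenance but inert — all features
  here are numeric, so ordered target statistics would be inert regardless.
* Calibration of predicted probabilities is not addressed; the 0.5 threshold
  is a convention, not an optimized operating point.
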