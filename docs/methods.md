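# Methods

## Scope and data model

One record per animal: species (dog/cat), raw breed and color strings,
gender, age in years, intake and outcome dates, outcome type (adopted /
returned to owner / euthanized) and shelter location. Species outside
dogs and cats are dropped at read time. Outcome type is **not** used as a
predictor: it deterministically fixes the target for euthanized
(very-high) and returned (low) animals, so including it would leak the
label. The predictor set is species, breed-derived size, color category,
gender, age bin and location.

## Binning rules

* **Stay days** = outcome date − intake date, capped at 365; a negative
  difference is an erroneous record for the cleaner, never clamped.
* **LOS classes**: euthanized → very high regardless of days; returned →
  low with the stay recorded as 0 (the raw stay is preserved in a
  separate `raw_days` field for reporting); adopted → low (≤ 8 days),
  medium (9–42), high (43–365). Day 8 closes the low bin so the partition
  is total.
* **Age bins** use half-open intervals [0,1], (1,3], (3,7], (7,10],
  (10,∞) — puppy/kitten, adolescent, adult, senior, super senior — so
  fractional ages land in exactly one bin.
* **Breed** keeps the first listed component ("Shih Tzu/Yorkshire Terr" →
  shih tzu), case-folded, with a trailing " mix" stripped; breeds outside
  the bundled breed→size table collapse to "other". Size is a table
  lookup (small/medium/large, AKC-style); "other" defaults to medium.
  The table ships as an editable two-column CSV.
* **Color** reduces to brown/black/blue/white/multicolor. Any string
  naming two or more colors (slash, comma, "and", or two known tokens) is
  multicolor; single tokens map through an editable synonym table
  (chocolate/tan → brown, gray → blue, …; inherently mixed coats like
  calico or tabby map to multicolor); an unknown single token defaults to
  brown and is logged, rather than inflating the multicolor class.

## Cleaning

Five strategies: median substitution (mode for nominal fields — a median
has no meaning on nominal data), unique-value substitution (code −1),
both again after discarding any variable whose missing fraction exceeds
50% (the threshold is configurable; "a significant number of missing
values" is otherwise unquantified), and whole-row removal. The generic
table-level implementation (`clean_frame`) follows these verbatim. In
the record pipeline, rows missing a target ingredient (either date,
outcome type) or a closed-vocabulary field (species, gender), and rows
with a negative stay, are removed under **every** strategy — imputing
them would fabricate labels or unbinnable values. The unique code for
age/location survives as "no known bin" and one-hot encodes to an
all-zeros block, which is the natural image of an out-of-range code in
indicator space. Counts always reconcile: n_input = n_output +
n_removed.

## Training and evaluation

80/20 random train/test split (seeded). Hyperparameters are tuned by an
exhaustive grid search under stratified 10-fold cross-validation; the
default grids are: trees 100–1000 step 100, learning rate {0.01, 0.05,
0.10}, minimum terminal-node observations 2–10 step 1, split candidates
2–10 step 2, ANN hidden nodes 1–8 (single hidden layer, logistic
activation, backpropagation, 500-epoch budget). Logistic regression has
no tuned parameters and exposes its fitted per-class linear predictors
f(class, i) = β₀ + Σ βᵥ xᵥ with softmax class probabilities. The CV
selection metric is macro-F1 — no single metric is canonical here, and
macro-F1 weights all four classes equally under heavy imbalance. Exact
CV-score ties keep the earlier grid point; grids are ordered
smallest-model-first, so ties favour the smaller model. A single-point
grid skips CV entirely. Tree induction, boosting and backpropagation are
delegated to scikit-learn; entropy and information gain are implemented
and audited here as utilities (brute-force enumeration in the tests),
not as a competing tree learner.

Evaluation is one-vs-rest from the 4×4 confusion matrix; zero
denominators yield 0 rather than NaN. Macro averages are unweighted
means over exactly four per-class values. Wall-clock training time is
reported but never asserted — it is hardware-dependent. Feature
importance treats each one-hot indicator column as a feature (names like
`size_category=small`, matching how category-level findings are usually
reported): permutation importance is the mean macro-F1 drop over R
seeded shuffles of one column; native importance is |coefficient| ×
column SD for logistic regression and impurity importance for the tree
ensembles, and is undefined for the ANN.

## Goal-programming relocation

The predicted LOS class is categorical but the goal constraint needs a
number, so an encoding is explicit and configurable: ordinal 1–4 by
default, or representative days per class (4, 25, 204, 365 — bin
midpoints, with the cap standing in for the open top bin). Any strictly
increasing mapping is accepted. Default scaling factors are f₁ = the
maximum encoded LOS score and f₂ = the cost bound u^RC, putting both
deviation terms on a roughly unit scale; multiplying both factors by the
same constant provably never changes the argmin (tested). Negative
deviations are computed and reported but never penalized — falling short
of an ambitious goal is free; default goals are the most ambitious ones
(p^s = low's score, p^r = 0) so deviations read directly as "how far
from ideal". Capacity is a snapshot for a single decision;
`ShelterNetwork.decrement` supports sequential batch assignment.
Feasibility enumeration is exact because exactly one shelter is chosen;
Z-ties break to lower relocation cost, then lexicographic shelter id.
Infeasibility is a reported status with per-constraint diagnostics
(capacity / LOS bound / cost bound per excluded shelter), not an error.
Transportation time is sometimes discussed alongside these criteria but
is not part of the formal two-goal model and is out of scope.

## Synthetic generator

Defaults emulate the published summary structure of multi-state shelter
data: dog share 63,790/114,256 ≈ 0.558; dog outcomes returned 43.3%,
euthanized 20%, adopted the residual (the adopted share is never printed
and is derived); cat outcomes adopted 46.1%, euthanized 20%, returned
the residual; stay days per (species, gender, outcome) cell from a gamma
distribution moment-matched to the published mean/SD (e.g. adopted male
cats 37.75 ± 40.78), truncated at 365. A gamma is used because every
published cell has coefficient of variation near or above 1 —
right-skewed, non-negative — which a gamma captures with two moments.
Intake dates are uniform over a year and outcome dates realize the drawn
stay exactly. Dog ages are drawn with an expected age that decays in the
drawn stay, reproducing the reported qualitative older-dogs-shorter-stays
association without disturbing the per-cell stay moments (no
coefficients for that trend are published, so only the sign is
emulated). The corrupted fraction (default ≈ 4.54%, the published
error-row share) picks distinct rows and gives each exactly one defect:
missing gender, age or color, or a negative stay.

What the generator does **not** emulate: any real dependence of stay on
breed, size, color or location (features and stay days are independent
given species/gender/outcome). Classifiers on unplanted synthetic data
therefore perform near chance — by design. Pipeline-recovery claims use
`plant_signal`, which rewrites outcome/days so a chosen binned feature
value implies a chosen LOS class with a stated probability. Planted
signals target a naturally rare class (high) in the tests: planting onto
the majority class (low, dominated by returns) would be undetectable by
permutation importance since the majority prediction already covers it.
Passing tests demonstrate that the pipeline recovers structure that is
present, not that real shelter data contains such structure.

## Numerical choices and problem sizes

* Information gain clamps tiny negative floating residue to 0 (the
  quantity is provably non-negative).
* Entropy requires proportions summing to 1 within 1e-9; 0·log 0 := 0.
* Goal identities are exact (max/complement construction), verified to
  1e-9 in tests.
* Benchmark-table macro averages are checked to the printed 4-decimal
  precision (tolerance 5.1e-5, half an ulp of the printed figure).
* Test and acceptance runs use desk-scale sizes chosen to keep the suite
  quick while leaving every statistical check well-powered: 600–2,000
  records for pipeline tests, 1,500 for planted-signal training with
  single-point grids, 20,000 for generator moment recovery (3-standard-
  error bands), 200 random networks (≤ 8 shelters) for solver
  optimality.

## Known limitations

* The bundled breed→size table covers ~85 common breeds; everything else
  is "other" → medium. No fuzzy breed matching beyond first-token +
  synonym lookup.
* Returned animals are always classed low with 0 days, even when the raw
  stay was long; the raw stay is kept but unused by the classifier
  target.
* The ANN has no native importance measure; use permutation.
* Single-animal optimization only: batch relocation is sequential
  (greedy), not a joint assignment problem.
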