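# Methods

`biogeoclim` reimplements, as a tested pipeline, a family of analyses used to
study the palaeobiogeography and climatic niches of Triassic pterosauromorphs
(pterosaurs + lagerpetids): dispersal–extinction–cladogenesis (DEC) models
with time-stratified climatic barriers, branch-wise latitudinal dispersal
accounting, multivariate niche statistics on palaeoclimate-model output, and
DOMAIN/Gower habitat-suitability mapping. This note records the models, the
parameters that matter, the numerical choices, and what the synthetic tests
do and do not demonstrate.

## Range-evolution model

Geographic ranges are non-empty subsets of K discrete areas (plus the
absorbing null range ∅). Anagenesis is a continuous-time Markov chain:

- expansion:  q(R → R ∪ {a}) = d · Σ_{b∈R} m(b, a),  a ∉ R
- contraction: q(R → R \ {a}) = e for each a ∈ R (a singleton contracts to ∅)

with d the dispersal rate (per source–destination pair per Myr), e the
extirpation rate (per area per Myr), and m(b, a) ∈ [0, 1] epoch-specific
dispersal multipliers (1 = no barrier). Ranges larger than a configurable
cap (default: no cap) are excluded from the state space. State order is
fixed (size, then lexicographic) so serialized output is stable.

Cladogenesis divides the parent range R between daughters:

- **DEC** — singletons copy themselves; widespread parents undergo subset
  sympatry (one daughter {a}, a ∈ R; the other R) or vicariance with one
  singleton daughter, all distinct ordered events weighted equally.
- **DIVALIKE** — vicariance into any ordered pair of disjoint non-empty
  subsets covering R; sympatric copying only for singletons.
- **BAYAREALIKE** — both daughters copy R.
- **+j** — founder events (one daughter {a}, a ∉ R) join the event set with
  relative weight j against weight 1 per non-jump event.

The tree likelihood uses Felsenstein pruning over range states. Branches are
split at epoch breakpoints; each segment's transition matrix is a matrix
exponential (an eigendecomposition fast path is used only when it
reconstructs the rate matrix to 1e-10, otherwise scipy's scaling-and-
squaring; segments < 1e-9 Myr are treated as identity). Partial likelihoods
are rescaled per node to avoid underflow; an underflowed likelihood returns
−inf. The root is conditioned on an unweighted average over non-null states
— a common, documented default; note this makes the log-likelihood of a
zero-rate model with identical tips ln(1/(2^K − 1)), not 0. Maximum
likelihood uses L-BFGS-B on log(d), log(e) (and j untransformed) with
bounds d, e ∈ [1e-12, 5], j ∈ [0, 3], from three deterministic starts
(10⁻³/10⁻³, 0.1/0.1, 1/0.1); all starts are reported in the diagnostics.
Marginal ancestral ranges come from an inside/outside pass and are validated
against brute-force enumeration on small trees.

### What the engine can and cannot estimate

On data simulated from the model itself, d is recovered well (factor-2
accuracy in essentially every 150-tip replicate). The extirpation rate e is
not: its maximum-likelihood estimate collapses to the lower bound at every
tree depth we examined, because cladogenetic subset sympatry and vicariance
supply small daughter ranges at no rate cost, leaving tip data nearly
uninformative about e. This mirrors the long-standing observation that DEC
extinction rates are chronically estimated near zero. Conclusions should
therefore rest on d, on model contrasts, and on reconstructions — not on ê.

## Barrier (dispersal-inertia) curves

For each 1-Myr bin, a time-stratified model multiplies dispersal across a
configured set of region pairs by ε inside the bin only (default ε = 0.1;
the default pair set separates the two Gondwanan regions from the equatorial
belt and Laurasia, encoding the low-latitude arid belt). Both the penalized
and the free model are re-optimized over (d, e); penalized fits warm-start
at the free optimum, and a fast mode evaluates them at the free optimum
without re-fitting.

Δ is reported as the one-sided statistic min(0, lnL_penalized − lnL_free).
The raw difference is not sign-guaranteed — the two families are not nested,
and a bin in which no lineage crosses the barrier can *favour* the penalty
(observed in practice at +0.0–0.5 log units) — but the scientific reading
("how strongly do the data demand crossing in this bin") is one-sided, so
support for the barrier is floored at zero and both raw log-likelihoods are
kept in the output. A schedule whose multipliers are all 1 (ε = 1) is the
free model by construction and reuses its fit, making Δ exactly zero there.
Sensitivity of the curve's shape to ε is exercised over {0.01, 0.1, 0.5} in
the test suite. A cumulative-window mode (penalty from the bin's start
onward) is available since the per-bin and windowed readings are both
defensible; per-bin is the default.

## Dispersal accounting

Nodes with a single-area state at marginal probability ≥ 0.5 (the
"overwhelming signal" threshold; configurable, exercised at 0.5/0.7/0.9)
take that area; otherwise the node takes the union of areas over states
within 0.1 of the best state's probability, with the arithmetic mean of
their proxy latitudes. Each area carries the palaeolatitude of a reference
locality as a proxy for the whole area (the seven-area continental scheme
uses the published locality values, e.g. Brazil −39.7°, western North
America +6.9°, so that branch implies a 46.6° displacement; the five-region
scheme carries representative band mid-latitudes as a package choice).
A branch whose endpoint latitudes differ is one event; its start age is the
parent node's age (branch-interior timing is unknowable; a midpoint option
exists). Events must start inside the Triassic window (251.9–201.4 Ma), so
Triassic-rooted branches ending in Jurassic tips count. Displacements are
credited to half-open 1-Myr bins [start, end); the accumulated curve is the
running total and the corrected curve divides by the running event count
(a per-bin-mean mode exists, since both readings of an event-corrected
curve are defensible).

## Niche statistics

Occurrences within 111 km of a same-taxon occurrence are collapsed to one
record (single linkage on great-circle distance, sphere radius 6371 km;
lowest specimen id kept; different taxa never merge). Each record takes
MAT, MAP, and the seasonal variations of temperature and precipitation from
the nearest land cell of its stage slice, falling back to the nearest land
cell within 5 grid cells for coastal points; records spanning several slices
take per-variable means and count once. Records whose stage range leaves
the modelled slice table (e.g. into the Hettangian) are excluded from
climate analyses, and lagerpetids straddling the Carnian/Norian boundary
belong to neither age group — these two rules reproduce the published group
sizes (23/9/17 from 54) on the shipped fixture.

PCA standardizes each variable to unit variance (SD with ddof = 1) and
keeps all components; signs are fixed by making each component's largest
loading positive. The permutation MANOVA uses the Pillai trace (Wilks is
selectable) of the group effect on the four scaled variables — scaled
variables rather than PC scores, as the ordination is for display; the
statistic is invariant to per-variable scaling in any case. p = (1 + #{perm
≥ obs}) / (1 + n_perm) with n_perm = 999 by default and a mandatory seed;
pairwise comparisons get Benjamini–Hochberg FDR. Wilcoxon rank-sum tests
are exact for samples of ≤ 20 without ties and use the tie-corrected normal
approximation otherwise. Quantiles use linear interpolation; raincloud
whiskers run from the quartiles to the extreme values (no 1.5·IQR fence),
matching the raincloud convention used in this line of work.

## Habitat suitability (DOMAIN)

Suitability of a cell is its Gower similarity to the environmentally
nearest training occurrence: per-variable terms |x−y|/range are clipped at
1, averaged over MAT and MAP, and subtracted from 1. Normalization ranges
are max − min over the training points united with the training-slice land
cells (the range base is ambiguous in the DOMAIN tradition; the choice is
recorded in map metadata). Calibration uses a compound occurrence set
centred on the best-sampled interval (the 217.8-Ma late Norian slice
anchors normalization): middle + late Norian occurrences plus Carnian
outliers for lagerpetids, and the full Norian for pterosaurs. Maps are
continuous in [0, 1]; no threshold is applied; sea cells are masked.

## Synthetic data

The generator produces every pipeline input with known truth, all
bit-reproducible under fixed seeds:

- **Trees** — constant-rate birth–death (defaults λ = 0.15, μ = 0.05 per
  Myr), run until the target extant count is first reached plus one further
  waiting time, extinct lineages pruned. The defaults give ~40–50-Myr root
  depths for 150 tips, matching a Middle–Late Triassic radiation.
- **DEC histories** — Gillespie simulation along branches with epoch
  multipliers and cladogenetic draws from the model's event table. Branch
  paths ending in ∅ are marked extinct-in-range and redrawn (≤ 100 tries):
  whole-history rejection is astronomically unlikely on large trees
  (per-lineage ∅-absorption is ~12% over a 45-Myr branch at d = 0.02,
  e = 0.01), so the generator conditions branch-wise on range survival.
  This conditioning slightly enriches surviving ranges and is shared by the
  recovery analyses.
- **Climate grids** — MAT falls linearly from ~32 °C at the equator at
  0.45 °C/deg; MAP of 1400 mm/yr with a 900-mm trough over a southern
  subtropical arid band (−30° to −10°); temperature seasonality grows with
  |latitude|; Gaussian noise per field; land/sea from thresholded random
  Gaussian bumps ("blobby" continents) or all-land.
- **Occurrences** — land cells weighted by a Gaussian niche density in
  (MAT, MAP) per clade (lagerpetids 30 ± 4 °C / 800 ± 300 mm — warm, dry;
  pterosaurs 24 ± 3 °C / 1400 ± 250 mm — cooler, wetter, echoing the
  contrast the statistics are meant to detect).
- **Survey-mimic fixture** — a deterministic 65-row specimen table that
  collapses to 54 occurrences (24 pterosaur / 30 lagerpetid) with 8
  two-stage records and niche groups 23/9/17, so the count-sensitive filter
  logic is testable offline. The five records that drop out of the grouped
  analysis are reconstructed as one pterosaur ranging into the Hettangian
  and four boundary-straddling lagerpetids; the real dataset's reasons may
  differ.

Because niches are Gaussian, gradients linear and continents random blobs,
passing tests demonstrate correctness of the machinery and calibration of
the statistics — not that real Triassic data satisfy these assumptions.
Problem sizes in the routine test run (60-tip barrier curves, 150-tip
recovery, 500 calibration datasets, 20 × 20 DOMAIN oracles) were chosen as
the smallest designs at which each property is cleanly identified.

## Known limitations

- ê is effectively unidentifiable from tip ranges (see above).
- The one-sided Δ discards "support for the barrier"; the raw difference is
  available in the output for readers who want it.
- Locality collapsing is O(n²) in specimens; fine for thousands, not
  millions.
- The DOMAIN model uses two climate variables by design; adding variables
  is supported but untested against the published maps.
- Suitability and niche analyses trust the input palaeocoordinates and
  climate grids; no plate rotation or GCM post-processing is performed.
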