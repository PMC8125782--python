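# Methods

## The model

A Drug Prescription Network (DPN) at ATC level L is built from the
per-patient *sets* of distinct codes observed during one observation
window. For a cohort of n patients, node *i* is any code with at least
one prescribing patient and carries Pᵢ = |{patients prescribed i}|;
the edge {i, j} exists iff C_ij = |{patients prescribed both}| ≥ 1.
Both weights are patient counts: repeat dispensations of the same drug
to the same patient are prescription *events* (they enter the
demography tables) but never inflate Pᵢ or C_ij. Codes are projected
between levels by prefix truncation (1/3/4/5/7 characters for levels
1–5); no registry lookup is performed, with an optional user allow-list
for strict validation. Co-prescription means co-occurrence anywhere in
the window; no temporal overlap of the two dispensations is required.
Degree-0 nodes are kept, and density and all averages use the full node
count including isolates.

"Incomplete or ambiguous" records are operationalised as: a missing
mandatory field, an unparseable ATC string (wrong length, wrong
letter/digit pattern, or an unknown anatomical group), a non-ISO date,
a sex outside {F, M}, or a birth year later than the dispensation year.
Patient age is computed once, at a single index date (default: the last
day of the observation window), because a 12-month window supports only
one static age pyramid; the date and the age bins (default 0–21, 22–64,
65+) are configurable.

## Metric panel

- density d = 2E/(N(N−1)); undefined below two nodes.
- degree k (unweighted); mean k̄ = 2E/N.
- Freeman betweenness, unnormalised, geodesic ties split equally.
- closeness Cl_i = 1/Σ_j dist(i, j) over reachable j, unnormalised;
  isolated nodes score 0, disconnected graphs are computed per
  component and flagged (`is_connected` in the summary).
- Newman assortativity r: Pearson correlation of end-point degrees over
  all oriented edge ends; reported as not-applicable (None/NaN) when
  the end-degree variance is zero — regular and complete graphs — which
  is distinct from the error raised on edge-free graphs.
- giant-component heuristics k̄ > 1 (existence) and k̄ > ln N
  (spanning), reported *alongside* the true component decomposition,
  since the random-graph criteria can disagree with the ground truth on
  structured graphs.

Weighted centralities need an edge-length convention, and the field
uses several. Three modes are provided: `unweighted` (length 1), `cij`
(length = raw C_ij, the stored-weight-as-cost convention of common
graph toolchains, and the default here) and `inverse-cij`
(length = 1/C_ij, strong co-prescription = proximity). The chosen mode
is recorded in every summary row. CV% uses the population
(n-denominator) standard deviation.

## φ thresholding

φ is the 2×2-contingency (binary Pearson) correlation, computed from
(n, Pᵢ, P_j, C_ij) and undefined when either drug reaches no patient or
every patient (zero variance); counts violating the Fréchet bounds
max(0, Pᵢ+P_j−n) ≤ C_ij ≤ min(Pᵢ, P_j) raise an inconsistency error.
Thresholding keeps edges with φ ≥ φ\*; since any φ\* ≥ 0 removes all
negative-φ edges automatically, no separate sign handling exists.
"Connected nodes" counts nodes of surviving degree ≥ 1 (not membership
of the largest component).

Retention curves are evaluated on a default grid of 50 log-spaced
points in [10⁻⁵, 1] — the decay spans several decades of φ\*, so log
spacing is the natural parameterisation — and both fractions are
relative to the unthresholded connected-node and edge counts. The
logistic A/(1 + exp((x − x₀)/s)) is fitted by bounded least squares on
x = log₁₀ φ\* with A fixed to 1 by default (curves start at full
retention; a free A ∈ (0, 1] is available). A flat fraction vector is a
degenerate fit (error); non-convergence is flagged but the parameters
are still returned. φmax is the argmax of node-curve − edge-curve,
located by dense evaluation on 4000 log-grid points and bounded local
refinement (tolerance 10⁻¹⁰ on x), reported on the φ scale.

## Stratified comparison

Layers are binary (0/1) adjacencies over a shared node universe — the
union of codes across the compared layers, with absent codes as
all-zero rows. The cross-layer matrix D[i][j] is the Euclidean distance
between the neighbourhood profile (adjacency row) of code i in layer A
and of code j in layer B; on binary rows D² is exactly the Hamming
distance. A female-vs-male matrix is not itself a dissimilarity over
codes (positive diagonal, slight asymmetry), so before clustering it is
coerced the way R's `as.dist` reads a matrix: triangles averaged,
diagonal zeroed. ward.D2 linkage is SciPy's Ward on the precomputed
distances, whose Lance–Williams recurrence (squared distances inside,
square-rooted merge heights) is exactly the ward.D2 variant; it is
cross-checked in the tests against a naive O(n³) Lance–Williams
reference. Flat clusters for a chosen k remove the k−1 highest merges,
with ids renumbered by dendrogram leaf order; when k is not given it is
chosen by maximising the mean silhouette width over k = 2..min(10, n−1)
and reported with its silhouette value.

## The simulator

The generator emulates the statistical structure the analysis assumes
in a one-year primary-care dispensation register:

- **Demographics** — female fraction 0.547; age strata 0–21 / 22–64 /
  65+ with patient weights 0.119 / 0.500 / 0.381.
- **Volumes** — per-stratum mean prescription counts 3.0 / 9.0 / 26.6,
  drawn as 1 + Poisson(mean − 1) so every patient has at least one
  event. These means were derived so the strata carry ≈ 2.4 / 30.1 /
  68 % of prescriptions and the overall mean is ≈ 15 events per
  patient, the regime typical of such registers.
- **Popularity** — drug choice follows a Zipf law over the catalog,
  weight ∝ rank^(−1.4); the exponent is configurable since no
  distributional form is canonical, and 1.4 reproduces the qualitative
  extremes of real registers (one dominant drug, a tail of codes
  prescribed to a single patient). Catalog order encodes popularity
  rank, which lets tests plant modules among unpopular codes.
- **Modules** — non-random co-prescription is planted by membership: a
  module is (codes, boost, share); a fraction `share` of patients joins
  the module and draws each prescription from its codes with
  probability `boost`, from the global law otherwise. This yields a
  known positive φ contrast within modules and ≈ 0 across, which is all
  the thresholding stage needs; no attempt is made at a full
  dependence structure (copula) across drugs.
- The catalog is generated with a separate `catalog_seed` so cohorts
  can be re-drawn over a fixed catalog; all other randomness flows
  from the single `seed` through one NumPy generator. Dates are uniform
  over the window; no within-window temporal structure, dosage or
  prescriber behaviour is modelled.

What passing tests on this generator show — and do not show: they
verify the machinery (counting, formulas, fits, clustering) and the
method's qualitative signatures (dense low-level networks, heavy-tailed
popularity, popularity–connectivity association, module recovery by
φmax). They do not certify magnitudes on real claims data: real
registers have correlated comorbidity structure, seasonal prescribing
and coding idiosyncrasies the simulator deliberately omits, so
data-dependent quantities (weighted centrality means, observed r,
φmax values) will differ on real inputs. One artefact of random
catalogs is that level-4 and level-5 networks nearly coincide, because
random level-5 codes rarely share a level-4 parent; real ATC catalogs
have far more sibling substances.

## Numerical choices and limitations

- Exact tie handling in geodesics relies on the edge-length arithmetic;
  the oracle tests use integer (and dyadic, for inverse lengths)
  weights so ties are detected identically by Dijkstra and by
  brute-force enumeration.
- Problem sizes in the test-suite and the acceptance script (cohorts of
  10²–4×10³ patients, catalogs of 60–800 codes) were chosen as the
  smallest scales at which every qualitative signature is stable across
  seeds.
- The φmax estimate inherits the variance of both logistic fits;
  on very small networks (tens of edges) the node curve is nearly flat
  until the last decade, and φmax is reported but should be read as
  order-of-magnitude only.
- Betweenness/closeness magnitudes depend strongly on the edge-length
  convention; cross-study comparisons must match conventions, which is
  why every summary row records the weighting used.
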