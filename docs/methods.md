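# Methods

## Repeat-unit convention

A repeat unit is a SMILES string with exactly two `[*]` wildcards, each
bonded to one heavy atom. Joining those two attachment atoms with a single
*virtual closure bond* reproduces, for every atom, the coordination it has
in the infinite chain, and counts the inter-unit bond exactly once per
unit. The closure bond can degenerate into a parallel edge (vinyl
polymers, whose attachment atoms are already bonded) or a self-loop
(single-atom units such as polymethylene `[*]C[*]`); the internal
multigraph representation handles both, and a self-loop correctly
contributes 2 to the degree, so the lone carbon of polymethylene has δ = 2.

Substructure matching runs on a "cyclized" molecule with the closure bond
installed, so functional groups that straddle the unit boundary — e.g. the
ester completed across the `[*]` ends in a polyester written as
`[*]OCC(=O)[*]` — are censused correctly. Ring perception, in contrast,
runs on the *linear* molecule: the closure bond represents the inter-unit
bond and never creates an intra-unit ring, and letting it participate in
ring perception would turn every backbone into a macrocycle and re-route
the smallest-ring set through chords of genuine rings.

The backbone is the shortest heavy-atom path between the attachment atoms
(the closure bond excluded; ties broken by the lexicographically smallest
index sequence, for determinism). Rings sharing at least two atoms with
that path are traversed by the chain, so all their atoms count toward the
backbone size N_BB by default; the alternative of counting only the
traversed arc is available as `fused_ring_policy="shortest_arc"`. Pendant
rings (sharing one atom or none) are side groups. N_SP ≤ N_BB always.

## Descriptors

22 features per polymer. Choices in the places where a verbal definition
needs a sharp edge:

* **δᵛ (valence delta).** δᵛ = Zᵛ − h for C, N, O, F and
  (Zᵛ − h)/(Z − Zᵛ − 1) for S, Cl, Br, Si, P. Elements outside that set
  raise immediately rather than produce a silently wrong δᵛ.
* **Connectivity indices.** ⁰χ = Σ δ^(−1/2) over heavy atoms and
  ¹χ = Σ (δᵢδⱼ)^(−1/2) over edges of the closure-augmented multigraph, the
  closure edge counted once; ⁰χᵛ, ¹χᵛ use δᵛ. For saturated acyclic
  hydrocarbons δᵛ = δ, so the valence and simple indices coincide — a
  property test.
* **Esters.** N_ester_n and N_ester_c count backbone esters (carbonyl
  carbon *and* ester oxygen on the backbone) with zero and one aromatic
  neighbour side respectively; backbone esters conjugated on both sides
  belong to neither and are reported separately. Side-group esters whose
  carbonyl carbon hangs off a backbone atom are acrylic-type esters and
  enter N_K with coefficient −3. All esters enter Nmv. Carbonate carbons
  are censused as carbonates only, never double-counted as two esters.
* **Ethers.** A divalent oxygen with two single bonds to carbon that is
  not an ester/carbonate oxygen. N_alkyl_ether additionally requires both
  neighbours to be sp³ non-aromatic carbons.
* **N_rot.** Backbone term: acyclic single bonds with both atoms on the
  backbone, the closure bond included (an all-ring backbone therefore has
  N_rot = 1, from the inter-unit bond alone). Side-group term: acyclic
  single bonds off the backbone whose two atoms each have ≥ 2 heavy
  neighbours. Terminal bonds (−CH3, −Cl, −OH) rotate nothing of the
  heavy-atom skeleton and contribute 0, and ring bonds contribute 0 —
  rigid or floppy rings restrict rotation in a different way than free
  single bonds, and we adopt the all-or-nothing rule rather than
  fractional ring contributions (the pluggable strategy hook allows the
  latter to be substituted).
* **Backbone indices.** BB_index1 = mean of δ/δᵛ over backbone atoms, a
  steric-hindrance measure; BB_index2 = mean of δ²/δᵛ, which separates
  backbone atoms with equal δ/δᵛ ratio but different heavy coordination.
  Both are injectable strategy objects so an alternative formulation can
  be swapped in without touching callers.
* **Atomic weights.** IUPAC conventional values to three decimals; M is a
  coarse feature and more precision is immaterial.

## Correlation suite

Features are z-scored before PCA, k-means and VIP — the descriptors mix
counts with g/mol, and a variance decomposition across such scales is
meaningless otherwise. Zero-variance columns are dropped with a warning.

* **PCA** loadings are unit-norm eigenvectors; each component's sign is
  fixed by making its largest-magnitude loading positive, so results are
  reproducible to the bit.
* **Variance diagnostic.** Variance fractions are compared between PCA
  without and with Tg appended. Appending a column necessarily changes
  the fractions at the O(1/p) renormalisation level (the denominator
  grows from p to p+1), so the diagnostic is read as profile similarity:
  the number of independent variance directions must not change, and the
  leading fractions must move only at that level. Exact invariance holds
  only in the fully redundant limit where one common factor drives every
  feature and Tg; the test suite asserts exactness there and the O(1/p)
  bound on rank-2 redundant data.
* **k-means cluster profile.** Tg never enters the clustering; clusters
  are profiled by their mean and SD of Tg afterwards and relabelled by
  ascending mean so the profile is invariant to the solver's label
  permutation. Default k = 4, seeded deterministic initialisation.
* **VIP.** VIP_j = Σ_k w_k·L_{j,k}·L_{Tg,k} over the first 5 components of
  the Tg-augmented PCA, w_k the variance fraction (an unweighted variant
  is available). Signed: it behaves as a pairwise correlation restricted
  to the dominant directions of the data.
* **Loading cone.** A feature is selected when its PC1–3 loading vector
  lies within a 30° half-angle cone around the Tg loading direction
  (sign +) or its antipode (sign −) — the computational counterpart of
  reading a shaded cone off a 3-D loading plot; the angle is
  configurable since any such cone is a visual convention.
* **Random forest.** 500 trees by default, impurity importances
  normalised to sum 1; unsigned. Replicate studies in the test-suite use
  100–200 trees — importance *rankings* stabilise well before 500 trees,
  and the replicate count matters more than the per-forest depth.
* **Consensus.** Pairwise, VIP and RF vote for their top six features by
  magnitude (ties at rank six are all included, with a warning); the cone
  votes for its members. Signs come from the signed methods; conflicting
  signs are reported as "+ and −", RF-only selections as "n/a".

## Manifold Tg model

Pipeline: z-score (train statistics only) → Isomap (k-nearest-neighbour
graph, geodesic shortest paths, classical MDS, dense eigensolver for
bit-determinism) → ordinary least squares of Tg on the embedding
coordinates. No regularisation: after the manifold step a linear model is
the simplest thing that works, and simplicity is robustness. The 20% test
split is drawn before any fitting and touches nothing — standardisation,
neighbour graph and regression see training rows only, verified by a
refit-without-test-rows bitwise-equality test.

* **n_neighbors** defaults to 5. Datasets containing repeated chemistries
  need a neighbourhood wider than the duplicate multiplicity, otherwise
  duplicates consume every neighbour slot and the graph disconnects; a
  disconnected graph raises an error naming the isolated records rather
  than silently embedding garbage.
* **n_components** defaults to 5-fold cross-validation over 2–8 on the
  training split (highest mean R², ties to the smaller dimension).
* **Out-of-sample embedding** uses the standard kernel (Nyström-type)
  extension rather than refitting the manifold. It reproduces in-sample
  embeddings to float roundoff of the geodesic kernel, i.e. predictions
  for a training row re-presented as new agree with its fitted value to
  ~1e−5 °C.
* **Extrapolation flag.** A prediction is flagged when the query's nearest
  training neighbour (standardised feature space) is farther than the
  95th percentile of training nearest-neighbour distances, or when the
  predicted Tg leaves the training Tg range. Manifold models interpolate
  well and extrapolate poorly; the flag operationalises that caveat.
* **Degenerate target.** Constant training Tg is reported as R² = 0 with
  a warning, zero slopes and the constant as intercept.
* **Serialisation** is a single JSON document (standardisation, training
  matrix, embedding, coefficients, split record); loading refits the
  Isomap deterministically from the stored training matrix, so a
  round-tripped model predicts identically.

## Synthetic data

Real polymer Tg compilations are multi-source (repeated measurements are
averaged on input, which is also where part of the noise budget comes
from) and are not redistributable here, so the test bed rests on a
hand-derived fixture set and three seeded generators with stored ground
truth.

* **Fixtures.** Eight classic homopolymers (polyethylene, polypropylene,
  polystyrene, PMMA, PVC, PEO, poly(methyl acrylate), PET) with expected
  values derived by hand from the defining formulas, cross-checked by an
  independent brute-force adjacency oracle in the tests.
* **Manifold generator.** Two latent coordinates (u, v) on a square; an
  S-curve bend (or a flat sheet, for the Isomap-equals-PCA limit) embeds
  them in 3-D, and a fixed mixing with orthonormal rows — columns
  rescaled to equal variance under the latent distribution — lifts them
  to 22 features. The near-isometry matters: per-column z-scoring then
  rescales the sheet uniformly instead of shearing it, making the design
  recoverable by construction. Tg = 75 + 120u + 55v spans roughly −100
  to 250 °C; Gaussian noise of sd `noise_sigma` (default 5 °C, the scale
  of multi-source measurement scatter) is added to Tg, and cross-
  correlated feature noise scales with the same σ so the noiseless limit
  is exact. What this generator does *not* emulate: discreteness of count
  features, cluster structure of chemical families, and heavy-tailed
  measurement error; passing tests therefore demonstrate recovery of a
  smooth latent law, not robustness to those real-data features.
* **Correlation generator.** Two Tg-driving factors, ten informative
  features, six correlated-nuisance features on unrelated factors, six
  pure-noise features, Tg noise sd 8 °C; optionally one feature is
  replaced by −Tg + 1% noise, which every method must flag with sign −.
* **Structure grammar.** Vinyl units `[*]CH2−CR1R2[*]` with R1 ∈ {H, CH3}
  and ~25 R2 side groups chosen so that chain flexibility and oxygen
  content vary independently (oxygen-free flexible alkyls alongside
  compact oxygen-rich groups) — otherwise the rotational-freedom signal
  is confounded with the heteroatom counts and importance methods land on
  proxies. Descriptors are computed by the real engine; the planted law
  is Tg = 90 − 30·N_rot + 55·N_aromaticring − 25·(BB_index2 − 2) + ε,
  ε ~ N(0, 8²) °C: flexibility lowers Tg, aromatic content raises it,
  backbone crowding (high-δ backbone atoms) correlates inversely — the
  sign structure the correlation suite is expected to recover. The
  coefficient magnitudes were chosen so the planted effect dominates its
  descriptor proxies across independent seed blocks, giving Tg in roughly
  −120 to 95 °C.

## Problem sizes and numerical choices

The default study sizes are n = 150 for the manifold model (80/20 split),
n = 60–80 polymers for correlation analyses (matching the scale of curated
Tg compilations), n = 500 rows for null-calibration replicates, and 20–100
seeded replicates for the stochastic guarantees. Tolerances: descriptor
counts are exact; connectivity indices agree with the brute-force oracle
to 1e−9; the Isomap-vs-PCA comparison on flat data is read at the 0.02 R²
level (graph-geodesic approximation error at these sample sizes); the
S-curve model is required to reach test R² ≥ 0.85 at σ = 5 °C with a
train/test gap ≤ 0.15. On the S-curve the noiseless test R² saturates
near 0.97 rather than 1: geodesics are approximated by k = 5 neighbour
graphs (larger k would shortcut across the fold), and that approximation,
not noise, is the floor. Temperatures are °C throughout; no Kelvin
conversion anywhere.

## Known limitations

* Stereochemistry, tacticity, copolymer sequence, crosslinking and 3-D
  conformational effects are outside the descriptor set; polymers
  differing only in microstructure are indistinguishable.
* The two backbone indices follow the verbal definition of a steric-
  hindrance parameter; alternative formulations can be injected but the
  defaults here are one concrete reading.
* The RF model is used for feature importance only, never as the
  predictor.
* Uncertainty reporting is limited to the binary extrapolation flag.
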