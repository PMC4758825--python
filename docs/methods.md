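# Methods

## Data model

An **observation stream** is an ordered list of sampling units over a fixed
roster of individual IDs (opaque strings — ring and colour codes are
alphanumeric, so no numeric coercion is ever applied). Units come in two
flavours:

* **group mode** — each unit is a non-empty set of individuals observed in
  the same group; under the gambit of the group, everyone in the unit is
  associated with everyone else.
* **period mode** — each unit is a symmetric 0/1 dyadic matrix over the
  roster: which pairs were observed associating during one sampling
  window. This is the representation the simulator emits.

Unit order is preserved exactly by the CSV readers and writers: the stream
is the resampling unit for the bootstrap and the swap substrate for the
permutation null, so chronology must survive serialization. Long-format
files order groups and roster by first appearance; duplicate
(group, individual) rows are collapsed with a warning; all-zero rows in
wide files (empty groups) are dropped with a warning.

The rarity filter (`filter_rare_individuals`, CLI `--min-obs`) counts
*units containing the individual*, not detections within a unit — "seen in
three flocks" rather than "three associations". It is idempotent and
leaves the input stream untouched.

## Association index

Edge weights are simple ratio indices. For a dyad (i, j) over all units:

    SRI = x / (x + y_ij + y_i + y_j)

with x = units where the pair was observed associating, y_ij = units where
both were observed but not together, y_i / y_j = units where only one was
observed. In group mode, co-occurrence *is* association, so y_ij ≡ 0. In
period mode an individual counts as "observed in a period" iff it has at
least one association in that period — dyadic sampling provides no other
presence signal; this convention is an interpretation, and it means a
truly present but fully unassociated individual is indistinguishable from
an absent one. The denominator telescopes to n_i + n_j − B_ij (units
containing i or j, with B the co-presence count), which is how the
implementation vectorizes it; dyads with a zero denominator get weight 0.

## Community detection and modularity

Communities are found by greedy agglomerative modularity optimization
(Clauset–Newman–Moore) on the positive-weight edges, via igraph's
fast-greedy implementation, cut at the merge step of maximum modularity.
The algorithm is deterministic for a fixed roster order. Isolated nodes
form singleton communities; an entirely edgeless network yields one
singleton per node with Q = 0 by convention. Any other detection method
could be substituted behind the same contract — the robustness machinery
only consumes a labelling.

Modularity uses the weighted mixing-matrix form with each undirected edge
counted once in each direction (so row and column marginals coincide):

    Q = Σ_x (e_xx − a_x²),  e_xy = (weight between x and y) / total weight.

A zero-total-weight network has Q defined as 0, with a warning. Tests
check this form against an independent explicit pairwise Newman–Girvan
double sum and against igraph's own modularity.

## Bootstrap and r_com

Each bootstrap replicate draws `n_units` units uniformly **with
replacement** (groups are the resampling unit; resampling individual
observations is a legitimate alternative not implemented here) and
restricts the roster to individuals present in the drawn units. Per
replicate the SRI network is rebuilt and communities re-detected; the
co-assignment matrix M and co-presence matrix C accumulate, and the
replicate's Q and community count are recorded. The co-membership
proportion is P = ΣM / ΣC elementwise where C > 0. Dyads never co-sampled
across all replicates get P = 0 and are flagged (`never_co_sampled`):
conditioning on co-presence leaves their proportion undefined, and zero
weight removes them from the assortativity sums harmlessly. Replicates
with fewer than two sampled individuals contribute nothing to M and C and
are recorded with Q = 0.

r_com treats P as a weighted network and computes the assortativity of
its weight with respect to the empirical labels,
r_com = (Σ e_xx − Σ a_x b_x)/(1 − Σ a_x b_x). It is invariant to label
permutation and to uniform scaling of P. Degenerate cases return NaN with
a warning: an all-zero P (no co-membership evidence at all) and a
single-community empirical partition (Σ a_x b_x = 1, undefined
denominator — a partition with one community has no assignment to be
robust about).

Defaults: 100 bootstrap replicates; the Q confidence interval is the
2.5/97.5 percentile interval of the replicate Q values — the simplest
defensible estimator, chosen because nothing in the problem constrains a
fancier one. The replicate community-count histogram is reported
alongside: a histogram concentrated on the empirical count signals
reproducible partitioning, a dispersed one signals replicates being cut
into different numbers of pieces even when the Q interval looks tight.

## Permutation null for Q

The data-stream permutation swaps one individual in one group with another
individual in another group (neither already a member of the target
group), preserving every group's size and every individual's observation
count. Swaps accumulate serially so the stream is increasingly
randomized; after each recorded step (default one swap per step, burn-in
0, both configurable) the network is rebuilt, communities re-detected and
Q recorded. The p value is one-sided with the add-one correction,
(1 + #{Q_rand ≥ Q_emp})/(1 + n_perm): is the stream more modular than its
sampling structure alone can explain? Q_emp is computed once from the
unpermuted stream. If no valid swap exists after bounded retries the
stream is returned unchanged with a warning (degenerate streams such as a
single group, or identical group memberships).

## Simulator

The generative model produces streams with known ground truth:

1. n individuals assigned to c communities i.i.d. uniformly — realized
   community sizes vary, and at small n a community can come out empty;
   the population is kept as drawn and the realized sizes are recorded.
2. Population fidelity p_w perturbed per individual by a Normal(1, 0.1)
   factor into attachments p_wi, clamped into [0, 1]. The upper clamp is
   part of the model; the lower clamp merely guards against negative
   probabilities (it cannot fire at the default sd unless p_w is extreme)
   and is logged when it does.
3. True dyadic probabilities e_ij = p_wi·p_wj within a community,
   (1−p_wi)(1−p_wj) between. p_w = 0.5 with sd = 0 is the structureless
   point (both products 0.25).
4. Detectability p_obs: each dyad associates in each period with
   probability p_obs × e_ij, independently across dyads and periods — no
   triadic closure, no temporal autocorrelation, no drift in membership.
5. 100 sampling periods by default, emitted as a period-mode stream.

These defaults (n ∈ 10–40, c ∈ 2–5, p_w on a 0.05 grid, p_obs ∈
{0.05, 0.2, 0.4, 0.8}, 100 periods, 100 bootstrap replicates) define the
validation conditions; `sweep` runs any sub-grid and emits a tidy table.
What the simulator does *not* emulate: unequal per-individual
detectability, spatially driven co-occurrence, group-size distributions
(periods are dyadic, not flock-shaped), and observer biases — so passing
simulation checks demonstrates the statistic's behaviour under random
sampling noise only, not robustness to systematic bias, which is exactly
why the permutation test is kept alongside r_com.

## Subsampling curves

`subsample_curve` draws random subsets of units **without replacement**
at sizes from `start` (default 50) in steps of 10 up to and including the
total (with-replacement draws at full size would not converge to the
empirical values), runs the full bootstrap pipeline on each, and averages
Q and r_com over (default) 50 replicate subsamples per size. Undefined
r_com values (degenerate partitions in very small subsamples) are
excluded from the mean.

## Numerical and design notes

* All randomness flows through a single `numpy.random.Generator`; every
  entry point accepts a seed or generator, and CLI outputs record the
  seed.
* Community labels are renumbered by first appearance in roster order, so
  partitions are comparable across runs.
* Swap-candidate selection sorts the eligible individuals before drawing,
  keeping permutation chains reproducible across processes (set iteration
  order is not stable across Python hash seeds).
* Equality tolerances: exact identities (SRI, Q on hand-computable
  fixtures, r_com boundary values) are asserted to 1e-12; oracle
  equivalence likewise; stochastic regime checks run at 20 replicate
  networks × 100 bootstrap replicates per parameter cell, a scale chosen
  to keep the full validation suite around a minute per cell while leaving
  wide margins around the expected means.
* The community-count histogram contrast is operationalized as: at high
  fidelity (p_w = 0.9, p_obs = 0.8) the modal replicate count equals the
  empirical count with essentially no dispersion; at weak fidelity under
  sparse sampling (p_w = 0.55, p_obs = 0.2) histograms disperse (a
  substantial fraction of replicates disagree with the empirical count)
  and the mode itself differs in a nontrivial share of streams.

## Limitations

* Only undirected networks; the directed generalization of the
  assortativity formula is not implemented.
* Only group resampling in the bootstrap; no jackknife.
* No restricted (stratified) permutations by time or location.
* Fast-greedy tie-breaking on knife-edge networks follows igraph's
  internal order; other implementations may cut ties differently, which
  can change individual assignments (not Q) on exactly balanced merges.
* r_com does not correct for the ≈0.2 floor that random association
  produces; values below ≈0.5 should not be read as evidence of robust
  structure, and small values are not "near-significant".
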