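# Methods

This note documents the statistical model behind `pdd`, the defaults and
why they are set as they are, what the synthetic generator does and does
not emulate, and the numerical conventions that make runs reproducible.

## The association statistic

All association strength is measured on *categorical* attribute values
(AVs). Numeric attributes are first quantized into equal-frequency bins
(default 3 — low/mid/high semantics for clinical variables; configurable
per attribute). Ties at a quantile boundary go to the lower bin so the
mapping is deterministic; a constant column collapses to one bin.

For an AV pair with marginals Occ(a), Occ(b), co-occurrence Occ(a↔b) and
T records, the adjusted standardized residual is

    SR(a↔b) = (Occ(a↔b) − Exp)/√Exp · (1 − Occ(a)·Occ(b)/T²),
    Exp     = Occ(a)·Occ(b)/T .

Two conventions deserve comment:

* The independence expectation Exp is the standard two-way product form;
  it is the only expectation consistent with "independent AVs".
* The trailing factor is implemented literally as a *multiplier*. The
  classical adjusted residual of Haberman instead divides by
  √((1−Occ(a)/T)(1−Occ(b)/T)); it is available as
  `PDDConfig(residual_variant="haberman")` for sensitivity analysis. The
  multiplier form shrinks large-marginal pairs, so SR saturates around 5–7
  for plausible implant strengths — a property that matters when sizing
  synthetic experiments (below).

AVs of the same attribute are structurally exclusive: their co-occurrence
is always 0 and the raw residual would be strongly negative. Those entries
are forced to 0 so within-attribute exclusivity never masquerades as
signal. The diagonal is 0. Missing cells contribute to no AV cover by
default (`missing_as_av=True` turns missingness into an explicit value).

Counts are never obtained by rescanning rows: the address table maps each
AV to its sorted entity-ID list and any AV set's support is the length of
the list intersection.

## Disentanglement

The K×K SR matrix is eigendecomposed (numpy `eigh`) *without centering or
rescaling*: rows are already standardized association vectors, and
centering would destroy that interpretation (this is also why generic PCA
implementations, which center, are not used). Each component PC_k gives a
rank-1 reconstructed matrix RSR_k = λ_k v_k v_kᵀ; summed over all k these
reproduce the SR matrix to numerical precision, which the tests assert at
1e-8.

A component is kept as a *disentangled space* when the maximum RSR entry
over distinct-attribute pairs exceeds the significance threshold (default
1.96). Signed positive values are tested — patterns are co-occurrences, so
anti-associations never gate significance (config flag `use_abs_rsr`
flips this). Eigenvector signs are fixed by making the largest-magnitude
loading coordinate positive, making DS numbering reproducible.

Two facts about this spectral step guided the synthetic design and are
worth knowing when interpreting real output:

* Two association blocks occurring on *mutually exclusive* entity sets are
  strongly anti-correlated and typically share one component, loading on
  opposite ends; the grouping step still separates them (their
  cross-entries are negative, hence never edges).
* A weak block (within-block SR ≈ 2–4) whose eigenvalue falls inside the
  bulk of the noise spectrum (edge ≈ 2σ√K) gets smeared across several
  components and can drop below threshold in every one of them. Detection
  needs the block eigenvalue comfortably above the noise edge.

## Grouping

Within a significant DS, AVs are linked when their reconstructed residual
exceeds the threshold (distinct attributes only). AV-Groups are the
connected components of size ≥ 2 — computed by union-find, so the result
is independent of edge insertion order, and every member has at least one
significant partner by construction. Isolated AVs are dropped.

Groups are refined into AV-Subgroups by agglomerative clustering on the
Dice overlap of the member AVs' entity covers,
sim(a,b) = 2|cov(a)∩cov(b)| / (|cov(a)|+|cov(b)|), with average linkage
(configurable single/complete) and a merge cutoff of 0.5: merging stops
when no inter-cluster similarity reaches the cutoff. Pairwise-AV
similarity with average linkage was chosen over recomputing cluster-cover
Dice during agglomeration; the two agree on the block-structured covers
the method targets, and the former is the standard formulation.
Ordinals are deterministic: groups by descending maximum |projection| of
members, subgroups by descending size then lexical AV order. Each subgroup
is a DSU, coded `[#DS #AVG #AVSG]`.

## Pattern discovery

Candidates are subsets (order ≥ 2) of one DSU's members, grown level-wise
with prefix joins; only zero-support sets and their supersets are pruned
(support is anti-monotone, asserted during growth), so the accepted set
equals exhaustive enumeration. A candidate P is accepted when

    SR(P) = R(P)/√V(P) > threshold,
    R(P) = (Occ(P) − Exp(P))/√Exp(P),
    Exp(P) = M·∏_{AV∈P} Occ(AV)/M,
    V(P) = 1 − ∏_{AV∈P} Occ(AV)/M .

Exp generalizes the pairwise independence expectation to mutual
independence; V mirrors the pairwise adjustment with the product running
over the pattern's constituent AVs (the product indexed otherwise is
dimensionally ill-posed). If some AV covers every entity, V ≤ 0 and the
raw residual is reported with a warning.

Accepted patterns pass a delta-closed filter: a pattern is dropped when an
accepted strict superset has support ≥ its own − delta. Default delta = 0
(classical closed patterns); this keeps a significant pair *and* its
significant triple when the triple loses support, but collapses
equal-support redundancy.

Pattern→class association is by plurality of the covering entities' labels
(ties unassigned). Plurality rather than absolute majority: the calculus
compares pattern counts per class, and a dominant-but-<50% class is still
the best-supported source.

## Entity clustering and the class-status calculus

Each entity joins the DSU maximizing sharing = |E ∩ AVSG| / |AVSG| (ties to
the lowest code); all-zero sharing goes to an explicit outlier cluster.

Per entity and mode, f[c] counts the accepted patterns of class c covering
the entity — every accepted pattern counts once, whatever its order.
With g the given class (wCL) or the cluster-majority implicit class (nCL):

| condition                          | status                   |
|------------------------------------|--------------------------|
| all f = 0                          | OL (outlier)             |
| f[g] = 0, unique argmax k          | Cra, readjusted to k     |
| f[g] = 0, tied argmax              | Und                      |
| 0 < f[g] < max f                   | Inc                      |
| f[g] = max f, tied                 | Und                      |
| f[g] > all others                  | Cor                      |

Integration of the two modes: Cor from wCL stands; a *confirmed*
readjustment — the target class attested by at least one accepted pattern
on that entity in the confirming mode — from either mode overrides
OL/Und/Inc in the other, wCL preferred on conflict; double-OL stays OL.
Accuracy is 100·(#Cor + #confirmed readjusted)/N; Inc, Und and OL count as
incorrect. The "before correction" figure credits Cor only.

In nCL the given labels are used solely to name each cluster's implicit
class (majority label; outlier-cluster members keep their own label since
a bucket of leftovers carries no class evidence) — discovery itself never
sees labels, which the tests verify by comparing pattern sets with and
without the label column.

## Synthetic data

The generator emulates the kind of dataset used to illustrate the method:
M entities × N attributes of i.i.d. uniform categorical background (a
skewed-marginal option exists for robustness tests), with AV associations
implanted on stated entity blocks, then optional corruption: implant cells
re-drawn at `cell_noise_rate`, labels flipped at `label_flip_rate`.
Background entities draw labels uniformly from the declared classes so
pattern-count nulls are symmetric. A manifest records every implanted
cell, true class and flipped entity, sufficient to recompute expected
covers without the pipeline. Everything is reproducible from one seed.

The bundled replica (`fig1_spec`) is 400 × 6 with alphabet size 5 and
three implanted associations with pairwise-disjoint AV sets:

* `{A2=P, A3=Q, A5=R}` on EID 75–129 (cover 55),
* `{A1=S, A4=T, A6=P}` on EID 100–189 (cover 90),
* `{A2=Q, A3=R, A5=P}` on EID 240–339 (cover 100).

The first two *overlap* on 30 entities: entanglement — associations from
different sources co-occurring in the same records — is the phenomenon the
method exists to resolve, and the overlap also keeps the blocks from being
mutually exclusive, which (per the spectral facts above) would smear the
weakest block below the significance threshold in a few percent of seeds.
Overlap entities take the smaller implant's label so every implant's cover
remains label-majority its own class. Implants are *exclusive* by default:
background entities that would complete a full implant AV set by chance
have one cell redrawn, so each implant's cover is exactly its stated
block (as in the illustrative address-table figure, where the triple's
intersection is exactly 55). A rare-group helper implants a small common
motif into one entity of each of several classes while keeping their
labels, emulating cross-class functional groups.

What the generator does **not** emulate: correlated background attributes,
class-conditional marginals, missingness mechanisms, or the joint
distributions of real clinical tables. Passing tests therefore shows the
machinery is correct and the statistics calibrated under uniform nulls —
not that real-data accuracy figures will be reproduced.

## Numerical conventions and limitations

* Pipeline is fully deterministic: no randomized tie-breaking anywhere;
  exports use sorted keys and stable orderings, and reruns are
  byte-identical (tested).
* Eigendecomposition tolerances: completeness 1e-8, orthonormality 1e-10.
* Problem sizes: the default test and acceptance runs use M = 400,
  K = 30 AVs and 20 seeds — sizes at which every stage is exact (no
  sampling or truncation anywhere).
* Degenerate inputs: a single-AV table, an all-missing column, an empty
  candidate set and conflicting implants raise errors naming the culprit;
  an empty knowledge base exports valid, empty files.
* Known limitations: per-component significance can miss associations
  whose eigenvalue hides in the noise bulk (weak or heavily entangled
  sources); the class-status calculus compares raw pattern counts, not
  supports or p-values, so a class attested by many low-order patterns
  outweighs one attested by a single high-order pattern; clustering
  assigns each entity to exactly one DSU even when it genuinely carries
  several sources (the pattern indicators in the entity space retain the
  full picture).
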