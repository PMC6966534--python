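# Methods

## Problem

Given a rooted clone phylogeny `T` whose leaves are sampled cancer
clones, each observed at an anatomical site (the primary tumor `P` or a
metastasis `M1…Mn`), infer the site of every ancestral clone. Each tree
edge whose endpoints are assigned different sites is a **migration
event**; collecting those events as directed site-pair edges (with
multiplicity) gives the **migration graph**, which summarizes how the
cancer spread — monoclonal vs polyclonal seeding, multisource seeding,
and reseeding of the primary.

## Parsimonious migration history (PMH)

A Sankoff dynamic program over the site alphabet computes, for every
node and site, the minimum number of migrations below that node. The
root is constrained to `P` (`pmh-con`); `pmh-unconstrained` drops the
constraint. Among all migration-minimal labelings (enumerated from the
DP tables up to a cap of 10,000; enumeration order is deterministic —
preorder, sites in alphabetical order) the labeling minimizing the
lexicographic objective (μ migrations, γ comigrations, σ source sites)
is selected.

**Comigrations.** A comigration is a group of migrations of separate
clones between the same ordered site pair that could have happened
simultaneously. Two same-pair migration edges can share a comigration
iff neither is an ancestor of the other, so per ordered pair the minimum
number of comigrations is the size of a minimum antichain cover of its
migration edges, which by Mirsky's theorem equals the length of the
longest ancestor–descendant chain. One DFS with a per-pair on-path
counter computes this for all pairs; γ is the sum over pairs.

**Polytomy resolution (`pmh-tr`).** Multifurcations may hide migration
structure. Each polytomy is refined into binary subtrees: exhaustively
over all (2n−3)!! rooted binary shapes for degree ≤ 6, and by greedy
pairwise joining of same-destination children above that (exact
resolution of an n-child polytomy is super-exponential). The refined
tree never increases μ relative to the unrefined tree.

## Bayesian biogeographic model (BBM)

Site evolution along a branch follows an equal-rate k-state Markov
model. A branch carrying `m` mutations has transition matrix

    P(m) = exp(Q · scale · max(m, ε)),   Q = equal-rate generator,

with `scale` = expected site changes per mutation (default **0.05**) and
`ε` = 0.01 guarding zero-length branches. The germline is kept as an
outgroup leaf observed at `P` on a zero-length branch, which pins the
root posterior to the primary without a hard constraint. Per-node
posterior site probabilities are computed two ways:

- `bbm-exact`: Felsenstein pruning (upward pass) plus a downward
  belief-propagation pass gives exact marginals under a uniform root
  prior.
- `bbm-mcmc`: Gibbs sampling of ancestral sites (single-node full
  conditionals), multiple chains pooled after burn-in (defaults: 3
  chains, 5M generations, sampling every 1,000, 1,000 burn-in samples
  per chain; chain seeds spawned from one seed sequence).

MAP sites (ties broken toward the parent's site, then alphabetically)
yield the point labeling and migration graph. Thresholding the
posterior (default 0.15) yields site *ranges*, from which dispersal
(range gain), diversification (site shared between parent and child)
and extinction (range loss) events are annotated per node.

The exact and MCMC estimators target the same marginals; tests verify
MCMC agrees with pruning to < 0.02 at 3×10⁵ pooled samples, and
pruning agrees with brute-force enumeration to 1e−9.

### Branch-scale sensitivity

The default scale 0.05 was fixed a priori (simulated histories realize
roughly one migration per ~10 mutations). A post-hoc sweep on a
40-dataset benchmark (master seed 0, exact posteriors) shows smaller
scales score somewhat higher:

| scale | 0.2 | 0.1 | 0.05 | 0.02 | 0.01 | 0.001 |
|-------|-----|-----|------|------|------|-------|
| mean F1 | 0.592 | 0.615 | 0.670 | 0.693 | 0.711 | 0.726 |

The default is deliberately **not** tuned to this sweep: as scale → 0
the model degenerates toward parsimony, and selecting the sweep optimum
would overfit the synthetic generator. The sweep is reported so users
calibrating to real data know the direction of the effect.

## Simulator

Four seeding scenarios of increasing complexity: `mS` (every metastasis
seeded by exactly one migration), `pS` (some metastasis seeded 2–3 times
from one source), `pM` (some metastasis seeded from ≥ 2 distinct
sources), `pR` (≥ 1 migration from a metastasis back to the primary).
Classification precedence when checking a realized graph: pR > pM > pS >
mS. Tumor-count classes: `m5` = 5–7 sites, `m8` = 8–11; 7–28 sampled
clones; 9–99 binary characters.

Generation proceeds in two stages: a migration-event plan satisfying
the scenario is drawn first (sources biased 0.7 toward the primary),
then a binary birth process realizes it — each migration splits an
existing clone of the source site, placing one child at the target.
Within-site clonal expansions are **interleaved in time** with the
migrations (an expansion of a site is placed uniformly at random after
the site is first occupied); placing all expansions after all
migrations creates long unsupported runs of primary-labeled internal
nodes that no real tumor would show. Every branch carries 1–6 private
mutations, so the character matrix is homoplasy-free and the
maximum-parsimony (perfect-phylogeny) tree equals the true tree — which
also means simulated trees are binary and `pmh-tr` coincides with
`pmh-con` on simulator output; polytomy resolution is exercised by
dedicated multifurcating fixtures in the tests.

**What the simulator does not emulate:** mutation-rate heterogeneity,
parallel/back mutation (homoplasy), sampling noise or unsampled clones,
anatomically structured migration routes (all site pairs are equally
reachable), and clone extinction.

## Evaluation

Inferred and true migration graphs are compared per ordered site pair
as edge **multisets**: TP = Σ min(multiplicities), FP = |G| − TP,
FN = |G*| − TP; precision, recall and F1 follow (undefined, with a
warning, when both graphs are empty). Errors are decomposed by path
type (P→M, M→M, M→P) with micro-averaged (pooled-count) rates across
datasets. Group mean F1 is compared between scenarios / tumor classes
with an unpooled two-sample Z-test and a Welch t-test.

## Problem sizes and numerics

- Benchmarks: 4 scenarios × 2 classes × 10 datasets = 80 datasets;
  exact posteriors run the whole benchmark in seconds.
- Sankoff DP is exact for any alphabet; optimal-labeling enumeration is
  capped at 10,000 labelings (a truncation flag is set if hit; the
  first-found lexicographic optimum is still migration-minimal).
- Exhaustive polytomy resolution is limited to degree 6
  ((2·6−3)!! = 945 shapes per polytomy); larger polytomies use the
  greedy joiner.
- All randomness flows from explicit integer seeds through NumPy
  `SeedSequence` spawning; benchmark runs are bit-for-bit reproducible.
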