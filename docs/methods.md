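# Methods

## Model

`clonesim` simulates bulk-sequencing data from a tumor evolving clonally
over time. A patient is a rooted tree of clones (the root's parent is
the germline, clone id 0) together with a matrix of cancer cell
fractions (CCFs, percent) — one value per clone per sampled time point.
CCF semantics are **cumulative**: a clone's CCF counts every cell
carrying its variants, including all descendants. This convention is
forced by the constraint system (the direct children of a clone may not
jointly exceed it) and by the VAF model (a heterozygous SNV in a diploid
region has VAF = CCF/2).

Three topologies are supported. Under *linear* evolution every new clone
descends from the most recently added clone. Under *branched dependent*
evolution clone c2 descends from the founder c1, clone c3 opens the
first branch (parent c1), and every later clone extends the chain or
branches from a uniformly chosen existing clone, on a fair coin. Under
*branched independent* evolution clone c2 arises directly from normal
cells (parent germline), and later clones extend the chain or open
another germline branch, again on a fair coin. Branched topologies
require at least 3 clones. High clone numbers under these models
approximate neutral (branched dependent) and punctuated (linear)
patterns, so no separate model keywords exist.

A valid phylogeny satisfies five constraints:

1. child CCF ≤ parent CCF at every time point;
2. the direct children of any clone sum to ≤ the parent's CCF, and
   clones descending directly from the germline sum to ≤ 100%;
3. eradication is permanent — once a clone's CCF reaches 0 it stays 0;
4. every clone reaches the detection threshold `minth` (default 2% CCF)
   at ≥ 1 time point;
5. every *pair* of clones differs by ≥ the minimum clonal distance
   `mindist` (default 4% CCF) at ≥ 1 time point. The pairwise reading
   (all pairs, not just parent/child) is deliberate: it is the only
   reading that guarantees every ground-truth cluster is separable.

## Phylogeny sampling

The founding clone's trajectory is drawn uniformly on [0, 100] per time
point, on a 0.1-CCF grid. Each subsequent clone picks its parent
according to the model and draws a trajectory below the feasible bound
(parent CCF minus the CCFs already granted to siblings). A candidate is
accepted only if all five constraints hold; up to 100 candidates are
drawn per clone, and after 100 failures the whole simulation restarts
with a new founding clone, up to 700 restarts, after which the
parameters are reported as infeasible. Zeros persist by construction
(once a trajectory hits 0 it is continued as 0), so eradication is
permitted but never forced.

The *proposal* distribution for non-founding clones matters only for
search efficiency — acceptance always re-checks every constraint — but
it matters a great deal: a plain uniform draw on [0, bound] halves the
CCF per chain step in expectation, so 9–10-clone linear phylogenies
would need on the order of 10⁴ restarts, far beyond the 700-restart
budget. Proposals therefore mix two modes per candidate: a uniform draw
on [0, bound] (diverse subclones, eradication) and an incremental draw
within 25 CCF of the bound (a new clone sweeping through most of its
parent, the common picture in stepwise linear evolution). The second
half of each clone's 100 attempts additionally draws one randomly
chosen time point directly from the feasible region — uniform over [0,
bound] minus the ±`mindist` bands around every existing clone, and
above `minth` where possible — so that in crowded phylogenies (10
clones at 3 time points) pairwise separation is achieved by
construction rather than luck. With this sampler every benchmark
configuration completes well inside the retry budget (worst observed
mean ≈ 80 restarts, ≈ 0.15 s, for branched independent evolution with
10 clones at 3 time points).

After the phylogeny is accepted, each clone receives one variant and the
remaining `n_variants − n_clones` variants are split uniformly at
random (one independent uniform clone choice per surplus variant).

Fine-tuning at the clonal level is exposed as `edit_phylogeny`: batch
edits (CCF values, parental relations, variant counts, adding/deleting
clones and time points) are applied to a copy and returned only if the
validator passes; otherwise the named violations are raised and nothing
is changed.

## Variants

CNVs are simulated first: uniform random location on the GRCh37
autosomes (length-weighted chromosome choice), length uniform on
[1, 10 000] bp, never overlapping another CNV. Every selected CNV type
(deletion, duplication, copy-neutral LOH) occurs at least once; the
remaining types are uniform. Clones are drawn uniformly among clones
with free variant budget. SNVs are then placed at unique uniform
positions *outside* every CNV (rejection sampling; the infinite-allele
assumption), filling each clone's remaining budget; reference and
alternative alleles are uniform distinct nucleotides (needed for VCF
export).

Overlaps exist only where configured. An overlap specification assigns
each CNV a number of overlapping SNVs and a scenario; the chosen SNVs
are repositioned uniformly inside the CNV and reassigned to a clone
drawn uniformly among those satisfying the scenario's clonal relation
(SNVs already in a compatible clone are preferred; a donor clone always
keeps ≥ 1 variant, and budgets are updated). The four scenarios and the
resulting genotype of the double-hit population at the SNV locus
(mutated copies m / total copies t):

| scenario              | relation                     | deletion | duplication | LOH |
|-----------------------|------------------------------|----------|-------------|-----|
| CNV first             | SNV clone ⊆ CNV clone        | 1/1      | 1/3         | 1/2 |
| SNV first, affected   | CNV clone ⊆ SNV clone        | 0/1      | 2/3         | 2/2 |
| SNV first, unaffected | CNV clone ⊆ SNV clone        | 1/1      | 1/3         | 0/2 |
| parallel              | disjoint branches            | —        | —           | —   |

(⊆ means descendant-of-or-equal; under *parallel* no cell carries both
variants, so the SNV population is 1/2 and the CNV-only population is
0/1, 0/3 or 0/2.) SNV-only cells are always 1/2, CNV-only cells 0/t,
and cells carrying neither — including the (1 − purity) normal fraction
— are 0/2.

The expected VAF is the population sum over all cell populations p at
the locus: VAF = 100 · Σ f·m / Σ f·t. Population fractions follow from
the cumulative CCFs (e.g. for *CNV first*: the SNV clone's cells carry
both variants, the CNV clone's remaining cells only the CNV) and are
scaled by purity. Without an overlap this reduces to
VAF = purity · CCF/2. Copy-neutral LOH under *CNV first* or *parallel*
leaves the locus copy number at 2 with an AB SNV genotype — such loci
are indistinguishable from CNV-free loci, which is why LOH barely
perturbs clustering tools.

Read depths are drawn per SNV per time point from a log-normal with
μ = ln(mean coverage) and σ = |ln 0.7| ≈ 0.357 (μ is the log-median, so
the median depth equals the requested coverage; the printed σ of the
source model is negative and only its magnitude is meaningful, since a
log-normal scale parameter must be positive; its value was calibrated
against targeted and whole-exome coverage profiles). The observed VAF
adds N(0, 1) noise *on the percent scale* to the expected VAF, clamped
to [0, 100] and rounded to 0.1; alternative read counts are
round(depth · VAF/100). The noise is additive-Gaussian rather than
binomial read resampling — a deliberate mirror of the simulation model
being reproduced; users wanting coverage-dependent VAF noise should
lower the mean coverage instead.

## Metrics

*Variation of information* between two clusterings of the same variant
set: VI = H(A) + H(B) − 2 I(A; B), computed from the contingency table
in natural log units (nats). VI is a true metric on partitions (zero iff
equal up to relabeling, symmetric, triangle inequality) and is bounded
by ln n_A + ln n_B.

*Discrete spectral distance* between clone trees: each tree (germline
node always included) is encoded as a directed parent→child adjacency
matrix, symmetrized (A + Aᵀ, clipped to {0, 1}), and its eigenvalue
spectrum is sorted; the shorter spectrum is zero-padded (allowing
truth-vs-reconstruction comparisons with differing clone counts) and
the Euclidean distance between spectra is returned. Symmetrization is
essential: the directed adjacency of a tree is nilpotent, so every
directed spectrum is identically zero. A graph-Laplacian spectrum is
exposed via `spectrum="laplacian"` for sensitivity analyses. Tools
reporting several candidate trees are scored by the mean distance
(`average_tree_distance`).

Note that DSD, being spectrum-based, is blind to relabelings *and* to
cospectral non-isomorphic graphs; for trees of ≤ 10 nodes this is a
minor effect and matches the intended use as a coarse dissimilarity.

## Benchmark corpus

`build_benchmark_configs()` enumerates 88 configurations around the
baseline (3 time points, 5 clones, 20 SNVs, 300x): time-point ladder
1–10, clone ladder 1–10, SNV ladder 5–50, coverage ladder
10x–2000x (all linear); twelve overlap configurations (deletion,
duplication, LOH × the four scenarios, each 20 SNVs + 6 CNVs
overlapping 1,1,1,2,2,3 SNVs, i.e. 10 of 20 SNVs affected); and the two
branched models with time-point ladder 1–10 and clone ladder 3–10.
The three parallel-scenario configurations use branched dependent
topology because a parallel SNV/CNV pair requires two clones in sibling
branches, which a strictly linear phylogeny cannot contain; for the
same reason CNV clones under the parallel scenario are drawn only among
clones that have at least one incomparable clone.

`run_benchmark` simulates 10 patients per configuration (880 bundles,
≈ 10 s on one CPU). Per-patient seeds are derived from the base seed
through a `SeedSequence` spawn key (dataset index, patient, retry) and
recorded in each patient's `params.yaml`, so any patient is individually
reproducible. A patient whose random phylogeny happens to leave the
overlap plan unsatisfiable (e.g. no free SNV in a compatible clone) is
re-simulated with the next retry sub-seed, up to 20 times, before being
recorded as a failure; failures carry dataset and patient ids and do not
abort the run.

## Serialization

A bundle directory holds `ccf_matrix.tsv` (clone, parent, n_variants,
CCF per time point; germline row omitted), `variants.tsv` (SNVs with
per-time-point depth/alt/VAF, CNVs with type and interval, overlap
annotations) and `params.yaml`. CCFs and VAFs are serialized with one
decimal — the precision at which they are simulated — and read counts
as integers, so export → import → export is byte-identical and import
re-validates every constraint (a hand-edited matrix violating the
parent bound is rejected with the named violation). Benchmark patients
additionally get `truth_clusters.tsv` and `truth_tree.tsv`; SNVs can be
written as a minimal multi-sample VCF 4.2 (GT/AD/DP, one sample per
time point).

## What the generator does and does not emulate

The generator reproduces the *statistical shape* of longitudinal bulk
variant-calling data: clone-structured CCFs, coverage-dependent depth
dispersion, scenario-correct VAF shifts under CNV overlap, and sample
impurity. It does not emulate sequencing-error base substitutions,
germline SNPs, alignment or callability artifacts, B-allele frequencies
of subclonal CNVs, or birth–death population dynamics between time
points. Passing tests therefore certify the constraint system, the
genotype arithmetic and the distributional parameters — not performance
of any downstream tool on real sequencing data.

## Numerical choices and degenerate inputs

CCFs live on a 0.1 grid; proposal draws are floored (never rounded up)
so a draw can never exceed its feasibility bound; constraint comparisons
use a 1e-9 tolerance. `minth = mindist = 0` disables constraints 4–5 and
generation then always succeeds for ≤ 10 clones × ≤ 10 time points.
A single clone at a single time point is the minimal valid simulation.
Tied eigenvalues in DSD are handled by sorting; zero-length reported
tree lists and mismatched clustering supports raise errors rather than
returning sentinel values.

## Problem sizes used in the test suite

The suite validates constraint satisfaction on 1000 seeded simulations
per model (sweeping the corpus's two axes: clones 3–10 at three time
points, time points 1–10 at five clones), distribution recovery on
10 000 read-depth draws, the exact multinomial split on 10 000
variant-count draws, and one full 880-patient corpus generation; the
whole suite runs in well under a minute on one CPU.
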