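# clonesim

Simulation of tumor clonal evolution for benchmarking subclonal
reconstruction tools.

Reconstructing how a tumor's clones evolve over a course of disease —
clustering somatic variants into clones and inferring the clonal tree
from bulk-sequencing samples — is largely automated by a zoo of tools
whose failure modes are hard to probe on real data, because the true
clonal structure of a real patient is never known. `clonesim` generates
ground-truthed synthetic patients for exactly this purpose: random
clonal phylogenies with cancer-cell-fraction (CCF) trajectories over
time, SNVs with simulated read counts, and CNVs that may overlap SNVs
under explicit evolutionary scenarios. It also implements the two
distances used to score reconstructions — variation of information for
clusterings and a discrete spectral distance for clone trees — and a
generator for an 88-configuration, 880-patient benchmark corpus.

## Model in brief

A patient is a rooted clone tree (germline root, id 0) plus a CCF
matrix over clones × time points, with cumulative CCF semantics (a
clone's CCF includes its descendants). Valid phylogenies satisfy:
child ≤ parent at every time point; children of a clone sum to ≤ the
parent (germline children to ≤ 100 %); eradication is permanent;
every clone reaches the detection threshold `minth` somewhere; every
pair of clones is separated by ≥ `mindist` somewhere. Generation is
rejection sampling with the retry budget of 100 candidate draws per
clone and 700 whole restarts.

SNV read depths are log-normal, depth ~ LogNormal(ln cov, |ln 0.7|).
The expected VAF of an SNV is the population sum over cell populations
p at its locus,

    VAF = 100 · Σₚ fₚ mₚ / Σₚ fₚ tₚ ,

where fₚ is a population's cell fraction and mₚ/tₚ its mutated/total
copies (normal and variant-free cells contribute 0/2). Without a CNV
this is purity · CCF/2; with an overlapping CNV the (m, t) of the
double-hit population depends on the CNV type and the scenario of
overlap (CNV first / SNV first affected / SNV first un-affected /
parallel). The canonical example: an SNV clone at CCF 100 % whose
wild-type allele is deleted in a 50 % subclone gives
VAF = (0.5·1 + 0.5·1)/(0.5·2 + 0.5·1) = 2/3 ≈ **67 %**, not 50 %.
Observed VAFs add N(0, 1) percent noise; alt reads = depth · VAF.

See `docs/methods.md` for the full model, the genotype table, and every
numerical choice.

## Worked example

Simulate one baseline patient — 3 time points, 5 clones, 20 SNVs plus
6 deletions overlapping 1,1,1,2,2,3 of them under the
"SNV first un-affected" scenario:

```bash
clonesim simulate --seed 11 --out demo --n-variants 26 \
    --cnv-types deletion --n-cnvs 6 \
    --overlap-multiplicities 1,1,1,2,2,3 \
    --overlap-scenario snv_first_unaffected
```

`demo/ccf_matrix.tsv` holds the ground-truth phylogeny — a linear
five-clone chain with its CCFs per time point:

```
clone	parent	n_variants	CCF_t1	CCF_t2	CCF_t3
1	0	3	87.5	84.9	99.2
2	1	10	64.2	83.1	95.9
3	2	3	39.9	30.6	49.0
4	3	3	10.9	4.2	38.6
5	4	7	5.5	3.4	21.1
```

and `demo/variants.tsv` the calls. The first rows are clone-1 SNVs
inside deletions of their wild-type allele:

```
id	kind	chrom	start	...	clone	overlap_cnv_id	scenario	depth_t1	alt_t1	VAF_t1	...
snv1	SNV	12	99841221	...	1	cnv5	snv_first_unaffected	636	401	63.0	...
snv3	SNV	3	178500518	...	1	cnv2	snv_first_unaffected	321	152	47.2	...
```

Without the overlap, snv1 (clone CCF 87.5 %) would sit near
VAF ≈ 44 %; the subclonal deletion of its un-mutated allele pushes the
expected VAF up (63.0 % observed at t1, rising to ~98 % at t3 as the
deletion clone expands) — precisely the signal that confuses clustering
tools which assume VAF = CCF/2.

Generate the benchmark corpus (~10 s on one CPU; every patient
directory also carries `truth_clusters.tsv` and `truth_tree.tsv`) and
score a reconstruction against the truth:

```bash
clonesim benchmark --out corpus --seed 1          # 880 patient bundles
clonesim metrics vi  --truth corpus/sim01/patient01/truth_clusters.tsv \
                     --test mytool_clusters.tsv
clonesim metrics dsd --truth corpus/sim01/patient01/truth_tree.tsv \
                     --test mytool_tree.tsv
```

(VI = 0 and DSD = 0 mean a perfect clustering / tree; both grow with
dissimilarity.)

From Python the same runs as:

```python
from clonesim import SimulationParams, simulate_patient, OverlapPlan

params = SimulationParams(n_variants=26, cnv_types=("deletion",), seed=11)
bundle = simulate_patient(params, overlap=OverlapPlan((1, 1, 1, 2, 2, 3),
                                                      "snv_first_unaffected"))
print(len(bundle.snvs), sum(1 for s in bundle.snvs if s.overlap))  # 20 10
```

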