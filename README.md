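# clonalfam

Likelihood-based clonal family inference for B cell receptor (BCR)
repertoires.

## The problem

Antibody diversity arises in two stages: VDJ *rearrangement* randomly
joins a V, D and J germline gene (trimming the joined ends and inserting
non-templated "N" nucleotides) to make a naive B cell, and *affinity
maturation* then diversifies each naive cell's descendants by somatic
hypermutation.  A sequenced repertoire is therefore a mixture of
lineages — *clonal families* — each descending from one rearrangement
event.  Reconstructing which reads belong to which family is the clonal
family inference problem, a prerequisite for lineage analysis, and it is
hard precisely where it matters: distinct rearrangements can produce
nearly identical naive sequences, while heavy hypermutation pushes true
relatives far apart.

`clonalfam` is aimed at immunologists and computational biologists who
need clonal partitions of heavy-chain repertoires, with explicit
likelihoods rather than fixed annotation-plus-identity heuristics.

## The model

Rearrangement is modelled as a hidden Markov chain with one state per
retained germline position of every V, D and J allele plus four N-addition
states (A, C, G, T) per junction; a path σ through the chain is an
annotated ancestor hypothesis, and germline states emit their own base
with probability 1 − μ at that position.  The same chain can emit k
sequences per step (a *multi-HMM*; k = 2 is a pair HMM), which constrains
all k sequences of a candidate family to a single shared annotation, so
the forward algorithm gives the marginal

    P(X) = Σ_σ P(X; σ)

of a sequence set X integrated over every possible annotation.  Two
clusters A and B are compared by the log likelihood ratio

    log P(A ∪ B) − log P(A) − log P(B),

positive when common ancestry explains the data better than independent
ancestry.  Agglomerative clustering repeatedly merges the pair with the
largest ratio while it exceeds a size-dependent threshold (18 natural-log
units for pairs, falling to 13 for merged sizes ≥ 6).  Hamming-fraction
gates between inferred naive sequences bracket the likelihood work:
pairs closer than 0.015 merge outright; pairs beyond a mutation-dependent
gate (0.08 at 5% sample mutation, 0.15 at 20%) are never evaluated.

Around this core sit: a Smith–Waterman pre-annotation stage (5:1 → 5:2 →
5:3 match:mismatch retry ladder, gap-open 30) that detects and *reverses*
somatic indels so the HMM sees indel-free sequences; Viterbi training of
all model parameters from the sample itself; three faster modes (*point*:
distance between joint Viterbi naive sequences at a 0.035–0.06 dynamic
threshold; *greedy*: centroid clustering of single-read naive sequences
at half that; *seeded*: full likelihood restricted to one family of
interest); a repertoire simulator with known truth (Yule trees,
per-site mutation rates, geometric/Zipf/box family sizes, indel
injection); and per-read precision/sensitivity/F1 evaluation.

## Worked example

```python
from clonalfam import (ClonalFamilyModel, SizeLaw,
                       default_parameter_set, fixture_germline_set)
from clonalfam.simulate import simulate_repertoire

germline = fixture_germline_set()
params = default_parameter_set(germline)
rep = simulate_repertoire(params, germline, SizeLaw("geometric", mean=10),
                          100, seed=1)
rep.write_fasta("reads.fasta")

model = ClonalFamilyModel.from_fasta("reads.fasta", germline)
results = model.fit(mode="full")
print(results.summary())
metrics = results.evaluate(rep.true_partition())
print(f"per-read precision {metrics.mean_precision:.3f}, "
      f"sensitivity {metrics.mean_sensitivity:.3f}, F1 {metrics.f1:.3f}")
```

prints

```
Clonal family inference results
==============================================
mode                                      full
reads clustered                            110
unannotatable reads                          0
sample mutation fraction                0.0509
clusters                                    14
largest cluster                             49
singletons                                   5
partition log probability             -3884.26
agglomeration steps                         96
==============================================
per-read precision 1.000, sensitivity 0.932, F1 0.965
```

The simulated sample holds 110 reads from 10 families at ~5% mutation.
The fit trains the HMM on the sample, runs 96 agglomeration steps and
stops at 14 clusters: every inferred cluster is pure (precision 1.0),
and 93% of each read's true family is recovered on average; the total
partition log probability lets you compare this stopping point against
any other step of the returned trajectory (`results.trajectory`).

The same pipeline is available from the shell:

```bash
clonalfam simulate --n-seqs 100 --mean 10 --seed 1 --outdir sim
clonalfam partition --reads sim/reads.fasta --mode full --outdir run
clonalfam evaluate --truth sim/truth_partition.csv \
                   --inferred run/partition.csv --outdir eval
```

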