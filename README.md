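# svdppcs

SVD-based **P**attern **P**airing and **C**hart **S**plitting: identify
conserved and divergent co-expression gene modules between two matched
expression data sets — two species, two tissues, or two conditions profiled
over comparable arrays (typically time series).

## Who this is for

Comparative transcriptomics asks which co-expression programs are shared
between two biological categories and which are specific to one. Generic
clustering applied to each data set separately answers neither question
well: cluster counts must be guessed, diffuse background genes distort
model selection, and cross-data-set correspondence is left to the analyst.
`svdppcs` addresses the comparison directly, at the level of expression
*patterns*, and chooses its own cutoffs from the data.

## The method

Given two gene × array matrices **A**⁽¹⁾, **A**⁽²⁾ over aligned conditions
(after two-way polishing — iterated column standardization and row
centring/L2 normalization):

1. **Pattern recognition.** Compute the SVD **A** = **U** diag(s) **V**ᵀ of
   each matrix. The right singular vectors **v**ⱼ (*eigengenes*) are the
   fundamental expression profiles over arrays; the left singular vectors
   **u**ⱼ hold per-gene loadings.
2. **Primary clusters (PCLs).** Assign gene *i* to the eigengene *j*
   maximizing the projection magnitude |sⱼ·u\_{ij}|, giving mutually
   exclusive clusters; keep the PCLs of the leading components (explicit
   *k* or a 60% variance target) and reallocate the rest by next-best
   projection.
3. **Pattern pairing.** Match eigengenes across the data sets by Pearson
   correlation of their profiles, tested with t = r·√((m−2)/(1−r²)) on
   m−2 df (defaults |r| ≥ 0.6, α = 0.01), one-to-one by descending |r|.
   A meaningful eigengene with no partner is paired with an empty-PCL
   component of the other data set, so its chart isolates one-sided
   patterns.
4. **Chart splitting.** For each pair, scatter the union of the two PCLs'
   genes with the paired left singular vectors as axes (x negated when
   r < 0). Four cutoffs *a* > 0 > *b* (y-axis) and *c* > 0 > *d* (x-axis)
   split the chart into ≤ 9 blocks; the centre block is discarded.
   Concordant corner blocks are **conserved** modules, edge blocks and
   discordant corners **divergent** ones.

Each cutoff is found by sweeping a line outward from zero and stopping
when the **SVD-p** of the genes beyond it first reaches φ = 0.05. For an
r × c gene-subset matrix with leading singular value s₁,

    SVD-p = P( F(ν₁, ν₂) > s₁² / (‖A‖²_F − s₁²) ),
    ν₁ = r + c − 2,   ν₂ = rc − 2r − c + 2,

an ad hoc F-calibration of the leading-component variance ratio that
balances cluster tightness against cluster size: a larger cluster needs
less tightness to reach the same SVD-p.

## Worked example

The package ships a two-species simulation benchmark: "mouse" and "human"
matrices of 338 orthologous genes × 18 hourly arrays with six planted
30-gene classes — a sine wave in both species (C1), mouse only (C2), human
only (C3); a gamma(9, 2) density in mouse (C4) and the same curve shifted
1.5 h in human (C5); a beta(6, 6) density in both (C6) — plus 218
pattern-free genes per species.

```python
from svdppcs import run_benchmark
run = run_benchmark(seed=0)
print(run.n_conserved, run.n_divergent)
print(run.recovery.to_string(index=False))
```

prints

```
2 4
class       module   classification  N1  N2  N3  precision   recall
   C1 pair(1,1).M1   conserved-down  30  30  30   1.000000 1.000000
   C2 pair(1,1).M2 divergent-1-down  30  57  30   0.526316 1.000000
   C3 pair(1,1).M3 divergent-2-down  30  54  29   0.537037 0.966667
   C4 pair(1,1).M2 divergent-1-down  30  57  26   0.456140 0.866667
   C5 pair(1,1).M3 divergent-2-down  30  54  25   0.462963 0.833333
   C6 pair(2,2).M1   conserved-down  30  33  30   0.909091 1.000000
```

Two conserved modules (the sine and beta classes, both shared) and four
divergent ones. N1 is the planted class size, N2 the matched module's
size, N3 their overlap: the sine-in-both class is recovered in full
(30/30), and every class reaches at least 25/30. The `examples/` scripts
walk through each capability (statistic, simulator, pipeline, coherence,
preprocessing) with commentary.

A thin CLI wraps the library:

```bash
svdppcs simulate --seed 0 --outdir sim/
svdppcs run --data1 sim/mouse.tsv --data2 sim/human.tsv --outdir out/
svdppcs svdp sim/mouse.tsv
```

`run` writes eigengene/variance/PCL tables, the pair report, Fig-style
cutoff traces, the gene-level module report with within-module correlation
columns, heatmap matrices, and a JSON summary.

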