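# dart-pathway

Denoising of prior pathway signatures against gene-expression data, and
per-sample pathway activity estimation over the denoised network (the DART
algorithm: *Denoising Algorithm based on Relevance network Topology*).

## The problem

Pathway activity in a tumour cohort is often estimated by averaging the
expression of a prior gene signature — genes annotated as upregulated
(σ<sub>i</sub> = +1) or downregulated (σ<sub>i</sub> = −1) upon pathway
activation, derived from in-vitro perturbation experiments or curated
databases. Much of that prior information is irrelevant in a new biological
context, and carrying it along dilutes the signal. DART tests the prior
against the data first and estimates activity only from the part that the
data support:

1. **Relevance network.** Compute Pearson correlations c<sub>ij</sub>
   between all pairs of signature genes, Fisher-transform them,
   y<sub>ij</sub> = ½ log((1+c<sub>ij</sub>)/(1−c<sub>ij</sub>)), which is
   N(0, 1/√(n<sub>S</sub>−3)) under the null, and keep pairs with two-sided
   p ≤ 10⁻⁴ as edges. The expected number of false-positive edges at this
   threshold is estimated by Monte Carlo: permute each gene's profile
   across samples and count surviving edges (below 1 on average over 1000
   runs at typical cohort sizes).
2. **Consistency.** The prior predicts each edge's correlation sign as the
   product σ<sub>i</sub>σ<sub>j</sub>. The consistency score is the
   fraction of edges whose observed sign matches; its significance comes
   from a randomisation null that redraws edge signs from a binomial with
   the network's empirical positive-sign probability.
3. **Pruning.** Edges contradicting the prior are removed and the largest
   connected component of what remains is the denoised pathway module.
4. **Activity.** Per-sample activity over the component of size M with node
   degrees k<sub>i</sub>, on z-score normalised expression z<sub>is</sub>:

   - simple average (used by the UPR-AV/PR-AV comparators):
     s<sub>s</sub> = (1/M) Σ<sub>i</sub> σ<sub>i</sub> z<sub>is</sub>
   - degree-weighted (DART):
     s<sub>s</sub> = (Σ<sub>i</sub> k<sub>i</sub>²)<sup>−1/2</sup>
     Σ<sub>i</sub> σ<sub>i</sub> k<sub>i</sub> z<sub>is</sub>

   Correlation hubs — the genes most embedded in the consistent network —
   get proportionally more weight.

The package also ships the two synthetic benchmark scenarios (SimSet1/
SimSet2: 24 genes × 100 samples, 40 inactive samples, three activity
levels), variational-Bayes mixture clustering of activity profiles with
ground-state accuracy scoring, the cross-cohort V consistency score for
inter-pathway correlation hypotheses, and permutation/t-test phenotype
association tests.

## Worked example

Everything below is reproducible from a fresh checkout (no external data):

```bash
dart simulate --scenario simset2 --seed 0 --out sim
dart network --expr sim/expression.tsv --sig sim/signature.tsv \
     --pthresh 1e-4 --fdr-runs 200 --seed 0 --out net
dart consistency --net net --sig sim/signature.tsv --nrand 1000 --seed 0
dart prune --net net --sig sim/signature.tsv --out pruned
dart activity --expr sim/expression.tsv --sig sim/signature.tsv --seed 0 \
     --out activity.tsv
```

which prints:

```
wrote 24x100 SimSet2 matrix to sim
expected false-positive edges at p<=0.0001: 0.050 (over 200 runs)
network: 24 nodes, 3 edges -> net
pathway    nG   nE   fE         fconsE   Pval
signature  24   3    0.010870   1.0      0.0
component: 3 genes, 3 edges -> pruned
wrote activity for 100 sample rows to activity.tsv
```

Reading: of the 24 signature genes only 3 edges are significant (about 1%
of the 276 possible pairs, against an expected 0.05 false edges, so the
network is real); all 3 edge signs agree with the prior (fconsE = 1.0,
randomisation p = 0), and the pruned component is exactly the triangle of
the three genes that faithfully track the simulated pathway (`pruned/
hubs.tsv` ranks them by degree: g01, g02, g03, each with degree 2). The
activity TSV holds one degree-weighted score per sample; inactive samples
(s001–s040 in this scenario) score low, e.g. s001 = −0.96.

The same steps run as a library:

```python
import dart

data = dart.simset2(dart.SimConfig(seed=0))
result = dart.run_dart(data.X, data.signature(), p_threshold=1e-4, seed=0)
result.component.nodes          # ['g01', 'g02', 'g03']
result.consistency.p_value      # 0.0
result.activity.scores          # one score per sample
```

`dart benchmark --scenario simset2 --reps 100 --seed 1 --out report/`
repeats the simulation, scores all three estimators, clusters each activity
profile with a variational-Bayes Gaussian mixture and reports ground-state
accuracies plus paired Wilcoxon comparisons.

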