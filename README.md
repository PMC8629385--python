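# devomics

Comparative developmental-transcriptome alignment and two-population
selective-sweep scanning, built for studies that profile the same tissue in
two breeds (or strains, lines, conditions) over a dense developmental time
course and resequence both populations.  The motivating setting is pig
skeletal muscle sampled at 27 time points (embryonic day 33 to postnatal
day 180) in a lean Western breed and an obese Chinese breed, but every
stage works on any two-condition time course plus a two-population VCF.

The toolkit answers four questions:

1. **Do the two conditions develop in step?**  For each time point,
   *development-associated genes* (DAGs) are genes with abundance
   RPKM > 1 and within-course Z score > 1.5 at that point.  Every
   time-point pair (i, j) across conditions is scored by the overlap of
   its DAG sets with an upper-tail hypergeometric test on the shared gene
   universe N:

       mapping score M(i,j) = −log10( min(1, m · P[X ≥ k]) ),   m = T_A·T_B

   A monotone staircase path from M(1,1) to M(T_A,T_B) maximizing the
   summed score — the *maximum trace*, found by dynamic programming with
   the recurrence S(i,j) = M(i,j) + max(S(i−1,j−1), S(i−1,j), S(i,j−1)) —
   gives the stage correspondence; its deviation from the diagonal
   measures which condition leads or lags development.
2. **Which genes distinguish the conditions?**  Per-phase two-group tests
   (|log2FC| ≥ 1, BH FDR ≤ 0.05), phase-specific one-vs-rest calls, and a
   per-gene condition × time interaction F-test for genes whose whole
   trajectory diverges.
3. **How is expression organised?**  CV-filtered (CV > 0.5) k-means
   co-expression modules with figure-of-merit selection of k, and
   lincRNA–miRNA–mRNA *ceRNA* triplets: R(miRNA, lincRNA) < −0.5,
   R(miRNA, mRNA) < −0.5, R(lincRNA, mRNA) > +0.5, all P < 0.05, joined
   through shared miRNAs and partitioned into the two opposing
   developmental-trend networks.
4. **Where has selection acted?**  Windowed (50 kb / 10 kb step)
   Weir–Cockerham FST (weighted, Σa / Σ(a+b+c)) and per-population
   nucleotide diversity θπ; windows jointly extreme in FST (top 5%) and in
   log2(θπ,A/θπ,B) (5% tails) are candidate sweep regions, merged and
   intersected with the gene annotation.  Genotype PCA, LD decay in
   100-bp bins, and a neighbor-joining tree on 1−IBS distances summarise
   population structure.

Because studies of this kind rarely ship desk-scale processed data, the
package includes first-class synthetic generators with known ground truth:
archetype-based expression time courses with an injectable developmental
lag, an anticorrelated miRNA layer, and Balding–Nichols two-population
genotypes with injectable sweeps.  Every analysis stage is validated by
recovering what the generators injected.

## Worked example

Align two simulated breeds at the default study conditions (2,000 genes,
27 time points, 60% of genes lagged by two time points in condition B,
log-noise sd 0.2):

```python
from devomics import *

cfg = ExprSimConfig(seed=1)
a, b, truth = simulate_expression(cfg)
u = shared_universe(a, b)
dags_a = call_dags(a, gene_stats(a), universe=u)
dags_b = call_dags(b, gene_stats(b), universe=u)
msm = mapping_score_matrix(dags_a, dags_b)
trace = maximum_trace(msm)
summary = summarize_mapping(trace)
print("trace total score:", round(trace.total, 1))
print("modal interior lag:", modal_interior_lag(summary))
print(summary.head(5).to_string(index=False))
```

prints

```
trace total score: 1313.3
modal interior lag: 2.0
A_timepoint  A_index B_span_start B_span_end  B_median_index  lag classification
        E33        0          E33        E33             0.0  0.0    synchronous
        E40        1          E33        E50             1.5  0.5        A-ahead
        E45        2          E50        E55             3.5  1.5        A-ahead
        E50        3          E55        E60             4.5  1.5        A-ahead
        E55        4          E60        E65             5.5  1.5        A-ahead
```

The trace is pinned to the matrix corners, so the first row is
synchronous; in the interior, condition A's time point i maps to B's
i + 2 (classification "A-ahead", positive lag): the aligner recovers the
injected two-step developmental lag of condition B.  `modal_interior_lag`
is the most frequent rounded lag away from the pinned edges — here
exactly the lag the generator injected.

The same analyses run from the shell on a YAML config:

```sh
devomics run-all --out run1 --seed 1      # simulate + all stages
devomics sweep --out run1                 # re-run one stage
```

Each stage writes TSV/BED/newick files plus a `manifest.json` recording
the resolved configuration, its hash and the seed; identical config and
seed reproduce every output byte for byte.

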