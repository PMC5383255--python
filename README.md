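# netprio

Network-based prioritization of candidate disease genes on a weighted
protein–protein interaction (PPI) graph, for computational biologists who
have a list of validated disease genes and want a ranked, screened list of
novel candidates.

## The method

Two complementary search routes operate on a STRING-style interactome in
which every edge carries an integer confidence score S(p₁, p₂) ∈ [150, 999]:

**Random walk with restart (RWR).** On the score-weighted network a walker
starts from the seed distribution P₀ (1/|S| on each validated gene) and
iterates

    P_{t+1} = (1 − r) · A · P_t + r · P₀

with restart probability r = 0.8 and A the column-normalized weighted
adjacency (A[i,j] = S(i,j)/Σₖ S(k,j), a column-stochastic transition
matrix), until the L1 change falls below 10⁻⁶. Non-seed genes whose
stationary probability exceeds a threshold pRWRp become candidates.

**Seed-pair shortest paths (SP).** On the transformed network with edge
weights w(e) = 1000 − S(p₁, p₂), Dijkstra's algorithm finds every
minimum-weight path between each pair of seed genes; the non-seed *inner*
nodes of those paths are candidates, each scored by its *betweenness* —
the number of seed-pair shortest paths containing it (a seed-restricted
count, not classical betweenness centrality).

Each candidate g then passes three screens:

1. **Permutation p-value.** The statistic is recomputed for 1,000 random
   seed sets of the same size; p(g) = Σδᵢ/1000 with δᵢ = 1 when the
   permuted statistic strictly exceeds the observed one. Survives when
   p < 0.05.
2. **Maximum interaction score.** MIS(g) = max{S(g, g′) : g′ ∈ S}.
   Survives when MIS ≥ p_MIS (thresholds 400/700/900 — STRING's medium,
   high and highest confidence).
3. **Maximum function score.** Every gene is encoded by a vector ES(g) of
   term-enrichment scores over GO/KEGG-like annotation sets; the
   association of two genes is the cosine
   M(g, g′) = ES(g)·ES(g′) / (‖ES(g)‖‖ES(g′)‖) and
   MFS(g) = max{M(g, g′) : g′ ∈ S}. Survives when MFS > p_MFS.

The thresholds (pRWRp, p_MIS, p_MFS) are tuned by leave-one-out
(jackknife) search over a parameter grid: each validated gene is held out
in turn, the full screened pipeline runs on the remaining seeds, and the
objective is the mean recall-weighted F1,

    F1-measure-R = recall · F1 = 2 · recall² · precision / (recall + precision),

which up-weights re-finding the held-out gene over precision. Tied optima
are reported in full. The **integrated result** is the union of the RWR
and SP putative sets, partitioned into both / RWR-only / SP-only.

A reproducible synthetic generator plants a dense high-score module in a
sparse background network (half the module poses as seeds, half as
held-out truth, with module-coherent annotations) so the whole pipeline
is testable without downloading an interactome.

## Worked example

```python
import netprio as npr

bundle = npr.generate()                      # planted-module benchmark
model = npr.RWRPrioritizer(bundle.network, bundle.seeds, bundle.annotations)
results = model.fit(n_perm=100, rng_seed=1)  # jackknife grid search
print(results.summary(top=3))
putative = results.putative_genes(n_perm=1000)
print(sorted(putative))
```

prints

```
RWRPrioritizer fit (10 seeds, 200 genes, 300 grid points, n_perm=100)

max mean F1-measure-R = 0.204365 achieved by 100 combination(s):
  pRWRp=1e-05, p_MIS=900, p_MFS=0.0  (recall=0.8000, precision=0.1173, F1-R=0.204365)
  pRWRp=2e-05, p_MIS=900, p_MFS=0.0  (recall=0.8000, precision=0.1173, F1-R=0.204365)
  ...
top 3 grid points:
method   prwrp  p_mis  p_mfs  mean_recall  mean_precision  mean_f1  mean_f1_r  n_folds
   rwr 0.00001    900    0.0          0.8        0.117262 0.204365   0.204365       10

['G0037', 'G0058', 'G0074', 'G0126', 'G0127', 'G0148']
```

The fit table says: across the 10 leave-one-out folds the best thresholds
re-found the held-out module gene 80% of the time at ~12% precision
(the other, equally valid, module genes count as false positives during
training), and many threshold combinations tie at that optimum — raising
pRWRp within its grid changes nothing at this network size, and the
function-score cut is not binding because module genes share coherent
annotations (MFS ≈ 0.96–0.99). The final putative list contains 6 of the
10 truly held-out module genes and no background gene.

The same flow works from the shell:

```sh
netprio simulate --outdir data/
netprio train --method rwr --network data/network.links.txt \
    --seeds data/seeds.txt --gmt data/annotations.gmt \
    --n-perm 100 --rng-seed 1 --out train.tsv
netprio integrate --network data/network.links.txt --seeds data/seeds.txt \
    --gmt data/annotations.gmt --rwr-prwrp 1e-5 --rng-seed 1 --outdir out/
```

Every command drops a JSON run manifest (resolved parameters, input
digests, RNG seed) next to its outputs; identical manifests reproduce
byte-identical TSVs.

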