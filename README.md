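# micronet

Reusable analysis pipeline for asking how a perturbation — such as an
early-life antibiotic course — reshapes the *interaction structure* of a gut
microbial community and its coupling to host immunity, from nothing more
than 16S OTU count tables and sample metadata.

Standard microbiome analyses compare community *composition*. `micronet`
instead reconstructs and compares the community's **association network**:
which taxa directly covary once all others are held fixed, how robust that
network is to losing its most connected members, which taxa are keystones,
and which taxa track a host phenotype (faecal secretory IgA) over time.
Everything is exercised end-to-end on synthetic communities with known
ground truth, so every stage has a recovery test.

## What it computes

**Network inference.** Counts are centred-log-ratio (clr) transformed
(`clr_j = ln p_j − mean_k ln p_k` per sample, the standard device for
compositional data) and a sparse conditional-dependence graph is estimated
by neighbourhood selection: an L1-penalised regression of every taxon's clr
profile on all the others, edges symmetrised by the OR rule. The penalty λ
is chosen by StARS stability selection — re-estimate the graph on many
subsamples along a λ path, give each edge an instability 2f(1−f) from its
selection frequency f, and select the smallest λ whose monotonised mean
instability stays below β = 0.05. The selection frequencies at the chosen λ
are per-edge **confidence scores**.

**Topology comparison.** Each network is summarised by how often every node
occupies each orbit of the connected graphlets on 2–4 nodes (orbits 0–14).
The Spearman correlation matrix of the 11 non-redundant orbits is a
size-independent signature; the Frobenius distance between two such
matrices is the graphlet correlation distance (GCD), and classical MDS
embeds a set of networks by their pairwise GCDs.

**Robustness and keystones.** Natural connectivity,
`ln((1/N) Σ_i exp(λ_i))` over the adjacency spectrum, is tracked while
nodes are removed at random (30 orderings), by degree, or by betweenness.
Keystone taxa are ranked by degree-rank + betweenness-rank (hubs that are
also bottlenecks).

**Cross-experiment edge recovery.** Stability-ranked edges from one
experiment are swept against the network of another over their common taxa,
reporting precision/recall/ROC and the maximum F1.

**Host association (multilevel sparse PLS).** Within-subject changes in
sIgA (ΔIgA, scaled) are regressed on within-subject clr variation
(`X_w = X − subject means + grand mean`) with soft-thresholded PLS
components; subject-level stability selection scores each taxon, and an
iterative filter keeps the top-m taxa that maximise out-of-sample r² on an
independent experiment.

**IgA-Seq.** The IgA coating index of a taxon is its relative abundance in
the flow-sorted IgA+ fraction over the IgA− fraction,
`ICI = (ra⁺ + ε)/(ra⁻ + ε)`.

## Worked example

```python
from micronet import (synth_graph, SyntheticTruth, synth_counts, make_precision,
                      NeighborhoodNetwork, keystone_taxa, natural_connectivity)

adj = synth_graph(25, "scale_free", n_edges=40, rng_seed=7)
truth = SyntheticTruth(graph=adj, precision=make_precision(adj, rng_seed=7))
table = synth_counts(truth, n_samples=300, rng_seed=7)

res = NeighborhoodNetwork.from_table(table).fit(seed=7)
print(res.summary())
net = res.network(table, min_prevalence=0.2)
```

prints

```
Neighborhood selection with StARS
  taxa: 25   lambda path: 30 values (0.6746 .. 0.0067)
  subsamples: 50 of size 173   beta: 0.05
  selected lambda: 0.3049 (index 5)
  instability at selection: 0.0379
  edges at selection: 35
```

i.e. StARS settled on the 6th λ of the path, where the graph estimate is
stable (instability 0.038 < 0.05) and keeps 35 of the 300 possible edges.
Against the known generating graph this estimate has precision 0.94 and
recall 0.82; `net.edge_density` is 0.117, `natural_connectivity(net)`
is 1.768, and `keystone_taxa(net, k=3).top` returns the planted hub first.

The same stages run from the shell:

```sh
micronet run-all --seed 1 --outdir out/      # full synthetic pipeline + manifest
micronet simulate / prep / infer / topology / attack / keystones / recover / spls / ici
```

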