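# aviannet

Graph-theoretic analysis of directed binary brain networks, built around
the first large-scale wiring diagram of an avian forebrain: the pigeon
(*Columba livia*) telencephalon connectome — 52 cytoarchitectonically
delineated regions and 344 directed connections compiled from four decades
of tract-tracing studies — which ships with the package as a reviewed
plain-text fixture.

The package is for computational neuroanatomists and network scientists
who want to ask, of any labelled directed binary graph, the questions
asked of mammalian cortical connectomes: is it a small world, is it
modular, which regions are hubs, and does it have a densely
interconnected central core?

## What it computes

For a digraph with adjacency $A$ (row = source), $n$ nodes and $m$ arcs:

- **Directed clustering** (Fagiolo): $C_i = \frac{[(A+A^T)^3]_{ii}}
  {2[d_i(d_i-1) - 2d_i^{\leftrightarrow}]}$ with $d_i$ the total degree
  and $d_i^{\leftrightarrow}$ the reciprocal-partner count; $\gamma$ is
  the network mean.
- **Mean path length** $\lambda$: mean directed BFS distance over finite
  ordered pairs (unreachable pairs excluded and counted).
- **Small-world indices** $\sigma = (\gamma/\gamma_r)/(\lambda/\lambda_r)$
  against two 200-sample null ensembles: Erdős–Rényi digraphs matching the
  average total node degree, and Maslov–Sneppen rewirings preserving every
  node's in- and out-degree ($\sigma_{io}$).
- **Directed assortativity** $r$: edge-wise correlation between source
  out-degree and target in-degree with pooled moments.
- **Structural motifs**: census of weakly connected induced subgraphs on
  3 and 4 nodes (13 and 199 isomorphism classes), with per-class z-scores
  $z_i = (Mo_i - \mu_i)/sd_i$ against rewired nulls.
- **Directed modularity** (Leicht–Newman):
  $Q = \frac{1}{m}\sum_{ij}\left[A_{ij} - \frac{k^{out}_i k^{in}_j}{m}\right]
  \delta_{c_i c_j}$, maximized by a multi-restart directed Louvain
  optimizer, with recursive sub-module analysis.
- **Hubs**: betweenness centrality $BC(h)=\sum_{i\neq j\neq h}
  g_{ij}(h)/g_{ij}$, a directed participation coefficient, and the
  hub rule (top-5 betweenness ∩ top-10 in-degree ∩ top-10 out-degree;
  connector hubs additionally have $P > 0.35$).
- **Core structure**: k-core decomposition by total-degree peeling with
  sub-shell bookkeeping; rich-club curve
  $\phi(k) = E_k/(N_k(N_k-1))$ normalized by rewired nulls; and
  knotty-centrality $KC(S) = \frac{E_S}{N_S(N_S-1)}\sum_{i\in S} bc(i)$
  with exhaustive/greedy knotty-center search.

A synthetic-data module (directed stochastic block model with an optional
hub overlay) provides planted-structure graphs so that every stage has a
parameter-recovery test.

## Worked example

```bash
aviannet reproduce-paper --out report.json --seed 1
```

prints (abridged):

```
Connectome: 52 regions, 344 directed connections
Clustering gamma = 0.3647; path length lambda = 2.4878 (200 unreachable pairs excluded)
Small-world: sigma = 0.9960 (ER null), sigma_io = 1.3213 (degree-sequence null)
Assortativity r = -0.1269
Motifs: 2328 3-motifs (null mean 3436), 22114 4-motifs (null mean 37684); 6 classes with z > 12
Modularity: Q = 0.3122 with 5 modules (module 1: Q = 0.1318, module 2: Q = 0.2031, ...)
Hubs: AD, AI, APH, CDL, NCL (connector hubs: AD, AI, APH, CDL, NCL)
K-core: full erosion at i = 11, innermost core i = 10; innermost sub-shell: AI, APH, CDL, HD, HL, NCL
Rich club: AD, AI, NCL
Knotty center: AD, AI, MD, NCL (KC = 0.3561)
```

Reading this: the pigeon telencephalon is far more clustered than its
degree-matched nulls ($\gamma = 0.3647$ vs $\approx 0.254$) at comparable
path length, i.e. a small world; it decomposes into five modules
($Q = 0.31$) of which the two largest split further; and five regions —
the premotor arcopallial fields AD and AI, the prefrontal-like NCL, the
parahippocampal APH and the corticoid CDL — are simultaneously the most
central (top betweenness), best connected (top degree), most erosion-
resistant (innermost k-core sub-shells), and spread their connections
across modules: a connective core. Three of them (AD, AI, NCL) are
mutually fully connected far in excess of chance (the rich club), and with
the dorsal mesopallium MD they form the knotty center, the subset that
concentrates shortest-path traffic while being densely intra-connected.

The same analyses are available per stage (`aviannet metrics global`,
`metrics motifs`, `metrics modularity`, `metrics hubs`, `metrics core`) on
any edge list, and `aviannet synth planted` generates benchmark graphs
with known ground truth. Library use mirrors the CLI:

```python
import aviannet as av

c = av.pigeon_connectome()
av.clustering_coefficient(c)          # 0.36468...
av.census(c, 4).total                 # 22114
p, q = av.optimize_partition(c, n_restarts=100, seed=1)
[r.region for r in av.classify_hubs(c, p) if r.is_connector_hub]
# ['AD', 'AI', 'APH', 'CDL', 'NCL']
```

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes, from the packaged fixture and nothing else, the headline
statistics of the analysis battery — clustering, path length,
assortativity, both motif totals, the k-core erosion index, the rewired
null path length and small-world index (200 samples), and the best
modularity over 100 restarts — and writes them as JSON keyed by target id.
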