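# abcifc

Detection of protein functional modules (complexes) in **weighted
protein–protein interaction networks** by intuitionistic fuzzy clustering
whose cluster centers are optimised with an **artificial bee colony** (ABC)
search — the ABC-IFC approach — together with fuzzy c-means (FCM) and plain
IFC baselines and the standard matching-based evaluation statistics.

It is aimed at systems-biology practitioners who have a weighted edge list
(confidence-scored interactions) and a reference complex catalog
(MIPS-style, one module per line) and want overlapping-capable, soft
module assignments without relying on shortest-path distances, which are
ill-defined on fragmented interactomes.

## Model

Nodes are proteins; each edge carries a raw weight, normalised to
w̄ = w / max w ∈ (0, 1]. Against a center set {v₁, …, v_c} every node *i*
gets an intuitionistic triple (membership, non-membership, hesitation)

    u_ij = (1 − π_ij) / (e^{d(i,vⱼ)²} + 1),   v_ij = 1 − π_ij − u_ij,

with a graph-aware distance d = 0 at the center, 1 − w̄ for interacting
pairs, and a finite cap d_max (default 2) otherwise. The hesitation π is
read off the interaction weight (π = w̄, `as_printed` mode; a
`complement` mode with π = 1 − w̄ is also provided). Nodes join their
argmax-membership cluster (optionally every cluster within a margin θ,
giving overlaps).

Center sets are scored by the clustering criterion (minimised)

    fval = (1/c²) Σ_{i≠j} sim(I_i, I_j) + 1/DEW,
    DEW  = (1/c) Σ_i (den(i) + dw(i)),

where `sim` is the normalised inter-cluster connection mass and
`den`/`dw` are the intra-cluster edge density and weight density. The
ABC search holds 2c candidate center sets ("nectar sources"); onlooker
bees swap one center for its information-richest neighbour (weighted
degree ranking, steered by `prob = 0.4`), acceptance is
strictly-improving, and sources failing more than `max_limit = 5` times
are abandoned to scout restarts.

Evaluation against a reference catalog uses the maximum matching score
MMS(C, F) = |C ∩ F|: precision MMS/|C|, recall MMS/|F|, their harmonic
mean (f-measure), and an upper hypergeometric tail P value for
functional enrichment.

## Worked example

Generate a planted-module benchmark (3 modules × 10 proteins, intra-module
edge probability 0.9 and weights U(0.6, 1), background probability 0.05
and weights U(0.1, 0.3)), cluster it, and read the report:

```sh
abcifc synth --k 3 --sizes 10,10,10 --p-in 0.9 --p-out 0.05 --seed 0 --out data/
# wrote data/network.tsv (30 nodes, 132 edges) and data/reference.txt (3 modules)

abcifc cluster --algo abc-ifc --c 3 --network data/network.tsv \
       --reference data/reference.txt --seed 0 --out run/
# wrote run/clustering.tsv and run/report.json
```

`run/report.json` (seed 0) contains:

```
objective.fval      0.99503   # best criterion value found (lower is better)
objective.sim_term  0.16913   # residual inter-cluster connection mass
objective.dew       1.21079   # mean intra-cluster density + weight
centers             P02, P15, P26
metrics.composite   precision 0.9667, recall 0.9700, f_measure 0.9683,
                    mean_p_value 3.66e-07
```

The search starts from a best random center set with fval 1.3125 and
ends at 0.9950; the recovered clusters match the three planted modules
up to one misplaced protein, and the tiny enrichment P value says each
cluster is far denser in its matched module than chance would allow.
`run/fval_trace.csv` holds the per-iteration best objective for
convergence plots, and `abcifc cluster --algo ifc|fcm` runs the
baselines on identical inputs.

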