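# sigscale

Multi-resolution **Significance** community detection for complex networks,
with a critical-point theory of its resolution, hierarchical benchmark
generators, and a multi-scale module-based disease-gene prioritization
pipeline (MSS / MSS+).

## The problem

Global quality measures for community detection suffer from *resolution
limits*: at a fixed resolution, communities below a scale set by the whole
network merge (first type), and in a resolution sweep large communities can
shatter before small ones become detectable (second type).  Significance is a
statistical measure that scores a partition by how unlikely its dense
communities are in a random graph:

```
S = Σ_s C(n_s, 2) · D(p_s ‖ p),
D(q ‖ p) = q ln(q/p) + (1 − q) ln((1 − q)/(1 − p)),
```

where `n_s` is the community's vertex count, `p_s` its internal link density,
and `p` the global link density.  The multi-resolution generalization
rescales the null density to `p̃ = γ·p`; `γ = 1` recovers plain Significance
and varying `γ` scans community structure across scales.  The package also
implements multi-resolution Modularity, `Q(γ) = Σ_s [m_s/m − γ(d_s/2m)²]`,
as the comparison baseline.

On a ring of `r` communities of `n_c` vertices (intra density `p_i`,
adjacent-community density `p_o`), merging adjacent communities becomes
favorable above a critical community number

```
r*_Significance = γ (p_i + 2p_o) · exp[(2H(p₂) − H(p₁)) / (2p₂ − p₁)],
r*_Modularity  = γ (p_i + 2p_o) / p_o          (γ = 1: p_i/p_o + 2),
```

with `p₁ = p_i`, `p₂ = (p_i + p_o)/2` and `H` the binary entropy.
Significance's critical number grows exponentially as `p_o/p_i` shrinks, so
its resolution vastly exceeds Modularity's on networks with well-separated
communities, and its merge path is affine (no "potential well" trapping
greedy search).

For gene prioritization, MSS scores each gene by the fraction of known
disease genes in its module, averaged over a `γ` grid of module partitions of
a protein network; MSS+ combines MSS linearly with random-walk-with-restart
(RWR) proximity scores.  Performance is measured by 5-fold cross-validated
AUC against genes never associated with the disease.

## Worked example

The classic second-type resolution-limit fixture: two 20-cliques and two
5-cliques on a ring joined by single edges (404 edges).  Plain Modularity
merges the two small cliques; Significance keeps all four blocks:

```python
import sigscale as sg
from sigscale import OptimizerSettings, ResolutionConfig, optimize

g, truth = sg.fb_graph(20, 5)
for measure in ("modularity", "significance"):
    part = optimize(g, OptimizerSettings(config=ResolutionConfig(1.0, measure), seed=0))
    print(measure, "Nd =", sg.community_count(part),
          " NMI vs truth = %.3f" % sg.compare_partitions(truth, part)["nmi"])
print("r* significance (p_i=0.9, p_o=0.05): %.3g" % sg.critical_r_significance(0.9, 0.05).r_star)
print("r* modularity  (p_i=0.9, p_o=0.05): %.3g" % sg.critical_r_modularity(0.9, 0.05).r_star)
```

prints

```
modularity Nd = 3  NMI vs truth = 0.938
significance Nd = 4  NMI vs truth = 1.000
r* significance (p_i=0.9, p_o=0.05): 1.57e+09
r* modularity  (p_i=0.9, p_o=0.05): 20
```

`Nd = 3` is the resolution limit in action — Modularity cannot keep the two
5-cliques apart at γ = 1 — while Significance recovers the planted structure
exactly.  The critical numbers quantify why: with these densities, loops of
up to ~1.6 billion communities survive under Significance, versus 20 under
Modularity.

A command-line surface mirrors the library:

```sh
sigscale benchmark loop --r 64 --n-c 16 --p-i 0.9 --p-o 0.05 --out bench/
sigscale detect --edges bench/edges.tsv --measure significance --out det/
sigscale compare bench/truth_L1.tsv det/partition.tsv
sigscale sweep --edges bench/edges.tsv --gammas 0.1,0.5,1,2 --truth bench/truth_L1.tsv
sigscale mss --network ppi.tsv --assoc assoc.tsv --disease "Cardiomyopathies"
```

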