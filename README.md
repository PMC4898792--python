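# hybcoal

Forward-in-time simulation of **hybridization networks** and **coalescent
gene trees**, a suite of **gene-tree discordance statistics**, and two
inference pipelines (multinomial scenario classification and semi-automatic
ABC) built on them.

## The problem

Multi-locus datasets routinely show gene trees that disagree with each
other.  Two biological processes dominate: **incomplete lineage sorting**
(ILS — ancestral polymorphism surviving across speciations, governed by the
coalescent) and **reticulate evolution** (homoploid hybrid speciation and
introgression).  Telling them apart from a collection of gene trees is hard
because both inflate discordance.  `hybcoal` is for researchers who want to
(a) simulate realistic mixtures of the two and (b) ask, via simulation-based
inference, which mixture best explains an observed set of gene trees.

## The model in brief

Species evolve forward in time under three memoryless processes: divergence
speciation at rate λ_S·N (Yule), proposed hybrid speciations at rate
λ_H·N(N−1), and proposed introgressions at rate λ_I·N(N−1).  A proposed
reticulation between species at genetic distance d succeeds with probability
F(d) — linear, step, quadratic, snowball (e^{−d²/T}) or exponential
(e^{−d/T}) decay with threshold/scale T — evaluated on a distance matrix
maintained throughout the run (off-diagonals grow by 2·Δt; hybrids get
γ-weighted averages of their parents' rows).  Rates and T can change across
epochs.  Each locus then picks one resolution of every reticulation
(probabilities γ / 1−γ) to give a *lineage tree*, inside which a coalescent
with per-pair rate λ_C runs (two lineages survive a branch of length t with
probability e^{−tλ_C}).  Profiles of gene trees are summarized by
discordance statistics — tree entropy TE, quartet entropy QE, split
incompatibility SI and its thresholded forms SI-k, rare splits RS, distance
to consensus DC, unique cherries/splits UC/US, and the internode-certainty
sums TC/TCA — which feed the classifiers and the ABC regressions.

See `docs/methods.md` for the full model description, conventions and
limitations.

## Worked example

The five-taxon example network has backbone (((A,B),D),E), an introgression
from E into D replacing 10% of D's genome, and a later hybrid speciation
founding C from the B and D lineages (60:40).  Exhaustively enumerating the
2² reticulation resolutions:

```
$ hybcoal fixtures
(((A:0.6,(B:0.4,(C:0.4)#H1:0[&gamma=0.6]):0.2):0.2,(D:0.4,#H1:0):0.4):0.2,E:1);
(((A,(B,C)),D),E);      0.54
(((A,B),(C,D)),E);      0.36
((A,(B,C)),(D,E));      0.06
((A,B),((C,D),E));      0.04
```

The first line is the network in extended Newick (the hybrid node appears
under both parents as `#H1`, with its genome contribution annotated); the
rest is the exact weighted lineage-tree distribution.  Weight 0.54 =
0.6 × 0.9 is the locus fraction routed through the B-side parent and
untouched by the introgression; the rare topology ((A,B),((C,D),E))
(weight 0.4 × 0.1 = 0.04) arises when a D-routed locus is also captured by
the earlier introgression.

Simulating gene trees and summarizing them, with `config.yaml`:

```yaml
success_function: step
epochs:
  - speciation_rate: 1.0
    hybrid_rate: 0.1
    coalescence_rate: 10.0
    success_threshold: 1.0e9   # step with huge T: success independent of distance
halting:
  max_species: 8
n_gene_trees: 20
```

```
$ hybcoal simulate --config config.yaml --out run --seed 42
simulated 8 species (max_species halt), 1 reticulations, 20 gene trees -> run
$ hybcoal stats --trees run/gene_trees.nex
TE      QE      SI      SI1     SI2     RS      DC      UC      US      TC      TCA
14.3862 3611.66 1540    966     576     1       66      7       13      1.30647 1.76087
```

Here TE = 14.4 (max would be 20·ln 20 ≈ 59.9 if all 20 gene trees shared one
topology) and DC = 66 say the profile is substantially discordant; SI
falling from 1540 to 576 as singleton and doubleton splits are thresholded
away (SI-1, SI-2) says much of the conflict is low-frequency — the ILS
signature rather than a strong reticulate signal.

The inference pipelines are driven the same way:

```
$ hybcoal classify-experiment --example 1 --seed 7 --out ex1   # confusion matrix + features
$ hybcoal abc-experiment --pilot 10000 --seed 7 --out abc      # summary-statistic fits
```

The library surface mirrors the CLI (`simulate_network`,
`simulate_gene_trees`, `enumerate_lineage_distribution`, `base_statistics`,
`fit_multinomial_stepwise`, `fit_summary_statistics`, `abc_rejection`, …).

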