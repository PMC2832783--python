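# pogf

Gene lists produced by different studies of the same disease — curated
databases, mutational screens, insertional-mutagenesis screens — often share
remarkably few genes.  `pogf` asks whether such lists are nonetheless
*functionally* reproducible: whether the genes unique to one list are tightly
wired, in a protein–protein interaction (PPI) network, to the genes of the
other.  It is a library plus command-line tool for systems biologists who
compare gene lists (cancer gene catalogues being the motivating case) and
need more than raw overlap counts.

## The scores

For two lists with lengths *l₁*, *l₂* and *m* shared genes, the directional
**POG** (Percentage of Overlapping Genes) scores are

    POG₁₂ = m / l₁        POG₂₁ = m / l₂

Two genes have a **PPI link** when they interact directly or share at least
one interaction neighbour.  A gene with *n* link partners among the *N* other
network genes is **functionally similar** to a list of *M* network genes when
its observed number *k* of links into the list is improbably large under the
hypergeometric model,

    p = Σ_{i=k}^{min(n,M)} C(M,i)·C(N−M,n−i) / C(N,n)   (similar iff p < 0.05).

The **POGF** score adds, to the *O* genes shared on the network, the *Of*
genes not shared but functionally similar to the other list:

    POGF₁₂ = (O + Of₁₂) / l₁        POGF₂₁ = (O + Of₂₁) / l₂

Chance expectations *E* are Monte-Carlo means over random list pairs of the
same lengths; each score is normalized as `(score − E)/(1 − E)` (chance → 0,
perfect → 1), and permutation p-values are the fraction of random scores
strictly larger than the observed one.  On top of the scores the package
provides FDR-controlled selection of candidates functionally linked to a
benchmark list, pathway-enrichment comparison of the selected/remaining
partition, and greedy selection of a non-redundant subset S ⊆ L with
POGF(L→S) = 1.

Because real PPI snapshots and curated gene lists cannot be redistributed,
the package ships a planted-module network generator (dense modules standing
in for pathways, over a sparse background) that reproduces the regime of
interest — near-zero overlap with high functional consistency — on demand.

## Worked example

```python
from pogf import (ModularNetworkSpec, generate_network, sample_lists,
                  compare_lists)

net, modules = generate_network(ModularNetworkSpec(seed=1))
list_a, list_b = sample_lists(modules, {0, 1, 2}, {0, 1, 2},
                              size=30, overlap=0, seed=2)
r = compare_lists(net, list_a, list_b, R=2000, seed=3)
print(f"POG12  = {r.pog12:.2f}   POGF12  = {r.pogf12:.2f}")
print(f"nPOGF12 = {r.npogf12:.2f}  (E = {r.e_pogf12:.3f}, p = {r.p_pogf12})")
```

prints

```
POG12  = 0.00   POGF12  = 0.83
nPOGF12 = 0.82  (E = 0.060, p = 0.0)
```

The two lists share no gene (POG = 0), yet 25 of the 30 genes of list A are
functionally similar to list B because both sample the same three planted
modules: POGF₁₂ = 0.83, far above its chance expectation of ≈0.06, with a
permutation p-value of 0 at 2000 repetitions (reported as `< 5e-04`).

The same analyses run from the shell:

```sh
pogf simulate --seed 1 --outdir fixtures/
pogf consistency --network fixtures/network.tsv \
     --list fixtures/listA.txt --list fixtures/listB.txt \
     --reps 2000 --seed 3 --out scores.tsv
pogf represent --network fixtures/network.tsv \
     --list fixtures/listA.txt --out subset.tsv
```

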