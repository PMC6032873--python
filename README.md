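# pollennet

Pollen DNA metabarcoding analysis, from raw amplicon read pairs to
pollen-transport networks and individual flower constancy.

`pollennet` is for ecologists studying what plants flower-visiting
insects actually carry pollen from. Given demultiplexed paired-end
barcode reads (rbcL-style amplicons) for individually sampled insects
and a rank-labelled reference library, it:

1. quality-trims, merges and length-filters read pairs (> 450 bp,
   strict);
2. assigns each read to a plant taxon by consensus over its best
   database hits — species when all retained top hits agree, genus when
   ≥ 60% share one genus, family/tribe when ≥ 90% share one family,
   otherwise unknown — with an optional allow-list of regionally
   recorded taxa;
3. builds per-insect pollen profiles (percent of identified reads per
   taxon) and site × period bipartite networks on a presence/absence-
   per-individual basis, with the specialisation indices **H2′**
   (network level) and **d′** (species level);
4. classifies each insect as a single-plant visitor (dominant taxon
   ≥ 90% of identified reads) or multi-plant visitor, and models the
   classification against season and sex with a binomial mixed-effects
   model (crossed random intercepts for site and insect species,
   Laplace approximation).

A synthetic-community module generates reference libraries, ground-truth
pollen mixtures and error-bearing paired reads, so the entire pipeline
is testable without any external data. See `docs/methods.md` for the
models and numerical choices.

## The core statistics

For an interaction matrix a_ij (individuals of insect species *i*
carrying plant taxon *j*, m = Σ a_ij, p_ij = a_ij/m, q_j = C_j/m):

    H2  = −Σ_ij p_ij ln p_ij
    H2′ = (H2max − H2) / (H2max − H2min)            ∈ [0, 1]

    d_i = Σ_j (a_ij/A_i) ln( (a_ij/A_i) / q_j )
    d′  = (d_i − dmin) / (dmax − dmin),  dmax = ln(m/A_i)   ∈ [0, 1]

where H2max/H2min (and dmin) are the entropy extremes attainable with
the observed marginal totals — exact for small networks, heuristic with
local polishing beyond.

## Worked example

```python
import pandas as pd
from pollennet import networks

mat = networks.InteractionMatrix(pd.DataFrame(
    [[4, 1, 0], [1, 3, 1], [0, 0, 2]],
    index=["E_pertinax", "E_horticola", "E_tenax"],
    columns=["Rubus", "Succisa", "Cirsium"]), site="CAD", period="late")

net = networks.h2_prime(mat)
print(f"H2={net.H2:.4f} H2min={net.H2min:.4f} "
      f"H2max={net.H2max:.4f} H2prime={net.H2prime:.4f}")
for sp in mat.counts.index:
    s = networks.d_prime(mat, sp)
    print(f"{sp}: d={s.d:.4f} dprime={s.dprime:.4f} (n={s.n_interactions})")
```

prints

```
H2=1.6326 H2min=1.2367 H2max=2.0228 H2prime=0.4963
E_pertinax: d=0.4197 dprime=0.4722 (n=5)
E_horticola: d=0.1612 dprime=0.1729 (n=5)
E_tenax: d=1.3863 dprime=0.7293 (n=2)
```

The network sits halfway between complete generalisation and complete
specialisation (H2′ ≈ 0.50). *E. tenax* is the most exclusive forager
(d′ ≈ 0.73): both its individuals carried *Cirsium*, which the other
species barely touch, whereas *E. horticola* spreads its interactions
almost in proportion to overall availability (d′ ≈ 0.17).

An end-to-end synthetic run from the shell:

```
pollennet all --output-dir out --seed 7 --n-insects-early 3 \
    --n-insects-late 6 --fixed-depth 40
```

writes per-stage TSVs (`profiles.tsv`, `network_metrics.tsv`,
`classifications.tsv`, `glmm_coefficients.tsv`, `pooled_proportions.tsv`,
`flower_unit_scores.tsv`) plus a `pipeline_log.txt` with per-stage read
accounting. Subcommands `simulate`, `assign`, `networks`, `classify`
and `report` run individual stages against saved intermediates.

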