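# lsgkit

Inferring regulatory function for uncharacterized **lineage-specific genes
(LSGs)** — genes with no detectable homologs outside a taxonomic lineage —
from microarray co-expression and promoter sequence analysis.

Because LSGs cannot be annotated by homology, their function must be read
off the company they keep: the genes they co-express with, the
transcription-factor binding sites (TFBSs) their promoters share, and their
position in a weighted co-expression network. `lsgkit` implements that
pipeline end to end:

1. **Expression filtering** — detection rules for a multi-tissue intensity
   panel (minimum 250 units in at least one sample, above the
   negative-control median, flagged present) and for a time-series ratio
   dataset (minimum 150 units, per-spot significance *p* < 0.05).
2. **Seed-based co-expression clustering** — grow clusters from seed
   transcripts at Pearson *r* ≥ 0.90, then greedily trim non-seed members
   until the average pairwise *r* ≥ 0.75. Tissue-preferential genes are
   those ≥ 2-fold above every other tissue.
3. **Diet-within-time contrasts** — per-gene OLS on (time, diet) cell means
   of log₂ ratios with Benjamini–Hochberg FDR across all gene × time tests.
4. **Promoter extraction** — strand-aware [−1000, +100] windows around the
   TSS from a soft-masked genome (1100 nt; no position 0), with hard-masked
   and unmasked views.
5. **PWM scanning** — TRANSFAC flat-file matrices scored Match-style:
   per-position information weights *I(i) = Σ_b f(i,b) ln 4f(i,b)*, matrix
   similarity MSS = (Current − Min)/(Max − Min), core similarity over the
   five most informative consecutive positions; defaults core ≥ 0.9,
   matrix ≥ 0.85, both strands.
6. **Composite TFBS enrichment** — ordered (A\*B) and unordered (A,B,C)
   pairs/triplets of distinct non-overlapping sites with inter-site gaps in
   [d_min, 250] for d_min ∈ {20, 50, 100}; one-sided Fisher exact test of
   cluster vs background promoter counts, BH-adjusted *p* ≤ 0.1, with a
   minimum observation count of five and a repeat-safety rule (masked
   predictions must recur in unmasked promoters).
7. **De novo motif discovery** — a discriminative Gibbs sampler (one site
   per sequence, ZOOPS) over widths 6–16 maximizing the foreground-minus-
   background best-site log-odds gap, and PWM-to-PWM matching against a
   known library by aligned-column correlation with a column-shuffle null
   (*p* < 0.01).
8. **Co-expression network** — unsigned power adjacency *a_ij = |r|^β*
   (β = 8 by default, or grid-selected by scale-free fit R² ≥ 0.8),
   topological overlap TOM, average-linkage module detection, and hub genes
   (top connectivity within a module at gene significance ≥ 1.2 on the
   −log₁₀ *p* scale and K/Kmax ≥ 0.95).

A seeded synthetic-data generator (`lsgkit.synthdata`) emulates all study
inputs — an 18-tissue panel, a 7-time-point × 2-diet peripartal liver
series, 1100-nt promoters with planted motifs/composites, a sharp PWM
library, and a toy genome with TSS annotation — so every stage is testable
against known planted truth without any external download.

## Worked example

Generate a synthetic study and run the pipeline:

```sh
lsg simulate --outdir demo --seed 17 --n-genes 120 --cluster-size 30
lsg scan --pwms demo/pwms.dat --fasta demo/fg_promoters.fa --out demo/hits.tsv
```

Or from Python, recover a planted diet effect:

```python
import numpy as np
from lsgkit import synthdata as sd
from lsgkit.exprdata import diet_within_time, mean_cluster_fold

sim = sd.SimConfig(seed=55, n_genes=200, noise_sd=0.3,
                   diet_effect_specs=[sd.DietEffectSpec(n_genes=200,
                                                        times=(1, 14), fold=1.8)])
_, ratios, truth = sd.gen_expression_timeseries(sim)
genes = truth.diet_effects[0]["genes"]
fold = mean_cluster_fold(ratios, genes, [1, 14], diets=("restricted", "adlib"))
res = diet_within_time(ratios)
hit = res.table[res.table.time.isin([1, 14]) & res.table.gene.isin(genes)]
print(round(fold, 3), round((hit["p_adj"] <= 0.1).mean(), 3))
```

prints

```
1.819 0.995
```

— the 1.8-fold under-expression planted on the restricted diet at +1 and
+14 days is recovered as a 1.819-fold difference, and 99.5% of the affected
gene × time contrasts are FDR-significant at 0.1.

The full pipeline (filter → cluster → promoters → scan → enrichment →
de novo → network) runs from one flat config file:

```sh
lsg run --config run.cfg --seed 17
```

and writes per-stage TSV/FASTA/JSON artifacts plus a `report.json` whose
contents are byte-reproducible for a fixed config and seed.

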