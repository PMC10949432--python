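# modulonkit

Reconstruction of a bacterial transcriptional regulatory network (TRN) from
an RNA-seq expression compendium, using independent component analysis to
extract **iModulons** — independently modulated gene sets — and a
genome-sequence arm that links them to promoter motifs and regulon
membership.

The package is aimed at microbial systems biologists who have a compendium
of logTPM expression profiles (tens to hundreds of samples over many
conditions), a draft regulator → gene table from curated sources, and a
genome annotation, and who want a tested, reproducible implementation of
the full workflow:

1. **Compendium QC** — sample exclusion (mapped-read and sequence-QC
   thresholds, replicate requirements), replicate-correlation filtering
   with group averaging at a Pearson-r threshold (default 0.80), and
   centering of each project on its reference condition.
2. **Robust ICA** — the centered gene × sample matrix X is decomposed as
   X ≈ M·A by FastICA run many times from random starts; gene-weight
   vectors are clustered by 1 − |r| and only components supported by at
   least half the restarts are kept (the cluster centrotype becomes a
   column of M, and A = M⁺X). A dimensionality sweep selects the component
   count at which every robust component is a genuine multi-gene
   component.
3. **iModulon extraction** — each column of M is thresholded by iterative
   D'Agostino normality testing into an outlier gene set; per-component
   explained variance σ² = 1 − ‖X − M_S A_S‖²_F / ‖X‖²_F; single-gene
   components are flagged; activities are Spearman-correlated and
   hierarchically clustered; differential iModulon activity (DIMA) between
   condition groups is tested against a log-normal null fitted to
   replicate-pair activity differences with Benjamini–Hochberg FDR.
4. **TRN enrichment** — Fisher-exact (hypergeometric tail) enrichment of
   every iModulon against every regulon, with iModulon recall
   (|shared| / |iModulon|) and regulon recall (|shared| / |regulon|)
   locating each pair in a well-matched / regulon-subset /
   regulon-discovery / poorly-matched quadrant plane.
5. **Operons, motifs, classification** — genes are partitioned into
   operons by intergenic distance (default 500 bp, strand-aware); a PSSM
   built from aligned transcription-factor binding sites (log-odds in
   bits against an explicit background) scores each operon promoter by its
   best window; and an elastic-net logistic regression (L1:L2 = 0.5),
   trained on SMOTETomek-balanced folds with operon-grouped stratified
   five-fold cross-validation, predicts regulon membership from motif
   scores, judged against a mean AUC-ROC benchmark of 0.8.

A synthetic-data module generates compendia, genomes, draft TRNs and
promoter sets with planted ground truth (modules, operon layout, motif
sites), so every stage has a parameter-recovery test.

## Worked example

```python
from modulonkit import (generate_compendium, generate_trn_table, run_ica,
                        extract_imodulons, enrich_regulons)
from modulonkit.qc import center_to_reference
from modulonkit.imodulons import explained_variance

comp, truth = generate_compendium(
    n_genes=200, n_conditions=20, replicates_per_condition=3,
    k_modules=5, noise_sd=0.3, replicate_rho=0.9, seed=11,
)
X = center_to_reference(comp).data
dec = run_ica(X, dimension=5, n_restarts=10, seed=11)
print(f"robust components: {dec.n_components}")
print(f"explained variance: {explained_variance(X, dec.M, dec.A):.3f}")

imods = extract_imodulons(dec.M, X=X, A=dec.A)
trn = generate_trn_table(truth, overlap_fraction=0.8, extra_genes=2, seed=11)
table = enrich_regulons({im.name: im.member_genes for im in imods},
                        trn, background=set(X.index))
```

prints

```
robust components: 5
explained variance: 0.938
```

and the enrichment table attaches one regulator to each component:

```
imodulon regulator  overlap      q_value  imodulon_recall  regulon_recall     quadrant
    ic_0        R1       16 2.102202e-17              0.8        0.888889 well_matched
    ic_1        R2       16 2.102202e-17              0.8        0.888889 well_matched
    ...
```

All five planted modules are recovered as robust components explaining 94%
of the compendium variance; each thresholds to its 20 planted member genes
and enriches for the matching draft regulon. The recalls are exactly what
the generator planted: the TRN kept 80% of each module (iModulon recall
0.8) plus 2 extra genes (regulon recall 16/18 ≈ 0.89), so every pair lands
in the well-matched quadrant.

The same stages are available from the shell:

```sh
modulonkit simulate --n-genes 200 --n-conditions 20 --replicates 3 \
    --k-modules 5 --seed 11 --outdir demo
modulonkit qc  --expression demo/expression.tsv --metadata demo/metadata.tsv \
    --sweep --outdir demo/qc
modulonkit ica --expression demo/qc/X_filtered.tsv --dimension 5 \
    --restarts 10 --seed 11 --outdir demo/ica
modulonkit run-all --config pipeline.yaml
```

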