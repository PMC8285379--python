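# pfcnet

Marine microbial communities carry out much of the ocean's biogeochemistry,
yet a large share of their proteins have no functional annotation.  `pfcnet`
is an analysis pipeline for protein catalogs predicted from
metagenome-assembled genomes (MAGs).  It groups proteins into **protein
functional clusters (PFCs)** — connected components of a sequence similarity
network — scores each cluster's annotation homogeneity and "darkness"
(no functional annotation in KEGG or eggNOG and no taxonomy below phylum),
asks which clusters' abundances are **predictable from the environment**
with repeated random-forest regression, and maps the environment-linked
clusters with a **constrained correspondence analysis (CCA)**.  Because the
method is annotation-agnostic, unannotated ("dark matter") clusters are
screened on equal footing with annotated ones.

It is written for microbial ecologists and bioinformaticians who have:
protein sequences (FASTA), pairwise hits (BLAST/DIAMOND outfmt 6), KEGG /
eggNOG annotation tables, MAG taxonomy, per-gene read counts, and an
environmental table for the same samples.

## The method in brief

1. **Similarity network.** An edge joins proteins *i*, *j* when their best
   pairwise hit has identity ≥ 80 % and coverage ≥ 80 % on both sequences.
   Connected components with ≥ 2 members are PFCs; the rest are singletons.
2. **Functional homogeneity.** For a cluster with `N_prot` proteins carrying
   `N_annot` unique annotation terms:
   `F_hom = 1` if `N_annot = 1`, else `F_hom = 1 − N_annot / N_prot`
   (floored at 0; undefined when no member is annotated).
3. **Abundance.** Per gene and sample,
   `abundance = count / (gene_length_nt × total_sequenced_reads) × 10⁹`,
   where the divisor is *sequenced* (mapped + unmapped) reads; cluster
   abundance is the mean over member proteins.
4. **Environmental screen.** After near-zero-variance filtering, each
   cluster's profile is modeled 10× on random 75/25 train/test splits with a
   500-tree random forest, tuning `mtry ∈ {5..9}` by 5-fold CV (RMSE).
   Clusters with mean cross-validated R² > 0.5 are *highly linked to the
   environment* (hlePFCs); > 0.25, *linked*.
5. **Biogeography.** A CCA of the hlePFC abundance table on the (optionally
   AIC-stepwise-selected) environmental variables, with a permutation test
   on the constrained-inertia fraction and per-pathway/taxon barycenters in
   ordination space.

A synthetic-data module generates every input with planted ground truth —
homolog families at controlled divergence, sparse annotations, dark
clusters, correlated mixed-type environment tables with missing cells, and
abundance profiles that are environment-linked, pure noise, or
near-constant — so the whole chain is testable without external downloads.

## Worked example

Run the full chain on a synthetic fixture:

```sh
pfcnet --seed 5 --outdir demo run-all
```

writes, under `demo/`, the generated inputs plus `pfc_membership.tsv`,
`pfc_scores.tsv`, `pfc_abundance.tsv`, `screen_results.tsv`,
`importance_summary.tsv`, and the ordination scores.  In Python:

```python
>>> from pfcnet.scoring import functional_homogeneity
>>> functional_homogeneity([{"K00001"}, {"K00001"}, {"K00001"}])
1.0
>>> functional_homogeneity([{"K1"}, {"K2"}, {"K3"}, {"K4"}])
0.0
>>> from pfcnet.screen import train_size, default_mtry
>>> train_size(93, 0.75), default_mtry(52)
(70, 7)
```

A score of 1.0 means every member shares one annotation term; 0.0 means all
terms differ.  With 93 samples, each screen repeat trains on 70; the
forest's default `mtry` for 52 predictors is 7 (floored square root).

Each subcommand (`simulate`, `cluster`, `score`, `quantify`, `prep-env`,
`screen`, `ordinate`) also runs standalone on files; see `pfcnet --help`.

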