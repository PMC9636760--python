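# chemotax

Chemotaxonomy from metabolite structural similarity: classify species into
clades using nothing but the chemical structures of the secondary
metabolites they contain.

The approach was developed for sulfur-containing plant metabolites
(glucosinolates, sulphated flavonoids, organosulfur volatiles, ...), where
the complement of compounds a plant produces carries a taxonomic signal:
eudicots and monocots concentrate different structural families, and
species sharing structurally coherent compound groups tend to group
together. `chemotax` implements that whole analysis as a reusable library
plus a thin command-line tool, and ships a synthetic-data generator with
planted ground truth so every stage can be validated exactly.

## The pipeline

1. **Fingerprints and Tanimoto similarity.** Each compound is a set-valued
   fingerprint (topological atom pairs computed from MOL/SDF structures via
   RDKit, or any precomputed feature-ID set). Pairwise similarity is the
   Tanimoto coefficient

   *T(A, B) = |A ∩ B| / |A ∪ B|* ∈ [0, 1],

   and compound pairs with *T* strictly greater than 0.85 become edges of an
   undirected similarity network (isolated compounds stay as countable
   single nodes). Species with fewer than two distinct compounds are
   filtered out beforehand.

2. **Overlapping density clustering.** Structural groups are extracted with
   a density–periphery clustering of the network. A cluster *k* with node
   set *N_k* and internal edge count |E_k| has density
   *d_k = |E_k| / (|N_k|(|N_k|−1)/2)*; a candidate node *n* attaches with
   cluster property *cp_nk = |E_nk| / (d_k · |N_k|)*, where |E_nk| counts
   edges between *n* and the cluster. Clusters grow greedily from
   high-degree seeds while *cp_nk ≥ 0.5* and *d_k ≥ 0.7* (minimum size 2),
   and a compound may end up in several clusters — overlaps are reported
   with the shared compounds.

3. **Species × group matrix and hierarchical classification.** A binary
   matrix M has M_ik = 1 when species *i* contains a compound of structural
   group *k*. Species are compared by Euclidean distance
   *d(i, j) = √Σ_k (M_ik − M_jk)²* and classified by agglomerative
   clustering (UPGMA by default); cutting the dendrogram gives a fine
   classification (k = 50 by convention) and the top-level clades (3 by
   default). The tree is exported as Newick, the network as Cytoscape
   SIF/GraphML.

4. **Pathway co-localization** (optional). Given a compound → pathway
   table, the package reports per-cluster pathway counts and the fraction
   of mapped compounds that share a pathway with another member of their
   structural cluster.

## Worked example

`examples/03_chemotaxonomy.py` generates 2 planted clades of 20 species
over 4 compound groups (5 % off-profile noise), runs the full pipeline and
scores recovery:

```
species x group matrix: 40 x 4
adjusted Rand index vs planted clades: 1.000  (1.0 = exact recovery)

clade composition (planted clade 1 labelled monocot, clade 2 eudicot):
 clade  n_species  n_monocot  n_eudicot  n_both  n_na
     1         20         20          0       0     0
     2         20          0         20       0     0
```

The matrix is 40 species × 4 structural groups (the density clustering
recovered the 4 planted groups exactly); the 2-cut of the dendrogram
reproduces the planted clades perfectly, so the adjusted Rand index is 1
and each clade is pure. The other scripts in `examples/` demonstrate the
similarity network, the overlapping bow-tie clustering, the pathway
statistic and the end-to-end run manifest.

The same workflow from the shell:

```bash
chemotax simulate --outdir sim --seed 1
chemotax run-all --outdir run \
    --fingerprints sim/fingerprints.tsv --relations sim/relations.tsv \
    --k 10 --n-clades 2
```

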