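# mitoload

Population-genetic analysis of annotated mitochondrial genomes: from GenBank
flat files to per-population nucleotide diversity (Nei–Li π), deleterious
mutation load (Pamilo–Bianchi–Li dN/dS with Kimura two-parameter correction
and codon-column bootstrap standard errors), MDS-based population
delineation, and cohort-level summaries (fold-differences, diversity bins,
diversity–load correlation with a log fit, and IUCN risk-group means).

A synthetic-data module generates fully self-contained test datasets —
coalescent genealogies, codon-aware mutation with a transition/transversion
bias and a nonsynonymous acceptance probability ω, optional two-deme
structure — emitted as GenBank-style flat files, so the entire pipeline runs
offline with known truth.

## Pipeline

The `mitoload` CLI chains six stages; every stage also has an importable
Python API (`mitoload.*`).

```bash
# 1. generate a synthetic species (or point --in at your own flat files)
mitoload simulate --n 10 --codons 3598 --theta 0.002 --omega 0.1 \
    --kappa 8 --demes 2 --split 5 --seed 17 --out data/flat

# 2. parse flat files, normalize gene names, apply the inclusion filters
#    (all 13 protein-CDS present; >=5 genomes per species)
mitoload extract --in data/flat --out data/extracted --min-genomes 5

# 3. translate (vertebrate mitochondrial code), align proteins, thread
#    codons back, mask ambiguous codons, concatenate the 12 heavy-strand
#    genes into a supergene (ND6 is excluded)
mitoload align --species-dir data/extracted/Synthetica_exempli --out data/aligned

# 4. variable sites -> VCF, 1-IBS distances, classical MDS,
#    silhouette-gated k-means with intermediate-record exclusion
mitoload structure --supergene data/aligned/supergene_Synthetica_exempli.fasta \
    --out data/structured --seed 17

# 5. per-population pi and dN/dS with 1000-replicate bootstrap SEs
mitoload stats --supergene data/aligned/supergene_Synthetica_exempli.fasta \
    --populations data/structured/Synthetica_exempli_populations.tsv \
    --reps 1000 --seed 17 --out data/stats.tsv

# 6. join with taxonomy + IUCN status; folds, bins, correlations, risk groups
mitoload cohort --stats data/stats.tsv --iucn iucn.tsv --out data/cohort --plots
```

Population calls can be corrected with `--overrides overrides.tsv`
(record_id &lt;TAB&gt; label), replacing interactive curation.

## Layout

- `src/mitoload/mitogenome_io.py` — flat-file parsing, gene-name synonyms, filters
- `src/mitoload/codon_alignment.py` — genetic code, translation, progressive
  protein aligner (BLOSUM62, affine gaps), back-translation, supergene
- `src/mitoload/population_structure.py` — variant table, VCF I/O, IBS
  distances, Torgerson MDS, population assignment
- `src/mitoload/molevol_stats.py` — complete-site deletion, Nei–Li π,
  site degeneracy, PBL pathway counting, K2P correction, bootstrap
- `src/mitoload/cohort_analysis.py` — folds, bins, correlations, risk groups,
  report rendering
- `src/mitoload/synthetic_data.py` — coalescent simulation, codon mutation
  with selection thinning, flat-file emission, truth tables
- `tests/` — unit, property and acceptance tests (`tests/test_acceptance.py`)
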