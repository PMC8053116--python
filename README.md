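# ribopause

Codon-resolution ribosome-pausing analysis and label-free co-IP interactome
enrichment, with a synthetic-data module that generates ground-truth inputs
for both pipelines so every stage is testable without external downloads.

## What it does

**Ribo arm** — starting from transcriptome-space footprint alignments (SAM),
transcript sequences (FASTA) and CDS coordinates (TSV):

1. `footprint_io` — load/validate inputs; inclusive size selection of
   footprints (default 26–34 nt of aligned reference span); replicate merging.
2. `psite` — per-read-length 5′→P-site offset estimation (mode of
   start-proximal distances, fallback 12 nt) and E/P/A-site codon assignment
   with frame QC.
3. `pauses` — per-codon P-site densities on transcripts with mean density
   ≥ 0.5 reads/codon; pause score
   `z = (counts[i] − max(background)) / (max(background) × 0.5)` over
   flanking windows; calls at z ≥ 10; codon-identity ranking and per-group
   (Arg/Gln built in) pause fractions across conditions.
4. `occupancy` — observed vs expected E/P/A-site codon frequencies
   (all covered transcripts, no coverage filter), unweighted or
   read-weighted expectation.

**Co-IP arm** — starting from a protein × sample LFQ intensity TSV:

5. `enrichment` — contaminant/reverse/only-by-site QC filter → log2 +
   "≥ 2 valid values in one group" filter → per-sample left-censored normal
   imputation (width 0.3, downshift 1.8 × sample SD) → per-protein two-sided
   Student's t-test with volcano coordinates.

**Synthetic data** — `synthetic` simulates transcriptomes (configurable
codon usage), footprint libraries (Poisson read counts, codon dwell
weights acting on the P- or A-site, injected pauses, length-specific
offsets, optional initiation peak) and quant tables (group effects,
logistic intensity-dependent dropout, flagged decoy rows), each with a
serialized truth record.

## CLI

```sh
ribopause simulate-ribo --out-dir sim --n-transcripts 50 --total-reads 100000 --seed 1
ribopause offsets   --fasta sim/transcriptome.fasta --annotation sim/transcripts.tsv \
                    --sam sim/footprints.sam --out offsets.tsv
ribopause pauses    --fasta sim/transcriptome.fasta --annotation sim/transcripts.tsv \
                    --sam sim/footprints.sam --out-dir pauses/
ribopause occupancy --fasta sim/transcriptome.fasta --annotation sim/transcripts.tsv \
                    --sam sim/footprints.sam --out occupancy.tsv --site all
ribopause compare wt=pauses_wt/codon_ranking.tsv mut=pauses_mut/codon_ranking.tsv --out cmp.tsv

ribopause simulate-coip --out-dir coip --seed 1
ribopause enrich --table coip/quant_table.tsv \
                 --groups bait=bait_1,bait_2,bait_3 \
                 --groups control=control_1,control_2,control_3 \
                 --out-dir enr/

ribopause run-all --out-dir run --seed 1   # both arms, manifest + checksums
```

Pass `--sam` multiple times to merge replicates. All outputs are TSV/JSON;
a `run-all` directory is byte-identically reproducible from its manifest's
config and seed.

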