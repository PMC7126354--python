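# splicecall

Reference-based discovery of single- and multi-exon protein-coding genes in
eukaryotic (metagenomic) contigs. The pipeline makes no assumption about
splice-site signals: it translates each contig in six reading frames,
extracts all stop-free fragments, finds local protein matches against a
reference database, and optimally joins compatible putative exons into gene
calls by dynamic programming. Redundant calls from homologous targets are
clustered and same-strand overlaps resolved, leaving one prediction per
locus.

## Pipeline stages

1. **translate** — six-frame extraction of stop-free fragments
   (`--min-length` codons, default 20). Fragments at contig edges without a
   bounding stop codon are kept.
2. **search** — affine-gap Smith-Waterman (BLOSUM62, gap 11/1, gapped
   Karlin-Altschul statistics λ=0.267, K=0.041) of fragments against the
   reference; hits with E-value ≤ 100 (`-e`) are kept. A shared-5-mer
   prefilter keeps desk-scale runs fast (`--exhaustive` disables it);
   externally computed hits can be supplied as BLAST/MMseqs2 tabular m8
   (`--hits-m8`).
3. **spliced_join** — the aligned part of each fragment (≥ 10 aa,
   `--min-exon-aa`) becomes a putative exon. Per (contig, strand, target),
   dynamic programming recovers the compatible exon set maximizing
   `S = Σ exon bits + Σ C(l) + log2(k!)` where `C(l) = -|l|` for target
   gaps/overlaps `l ≠ 1` and 0 for perfect adjacency (`l = 1`); the call
   E-value is `2·D·2^(-S)` with D the total reference residue count.
   Compatibility requires matching contig/target order, a contig gap in
   [15, 10000] nt, and target overlap ≥ -10 aa. Calls are filtered at
   E ≤ 1e-4 (`--call-evalue`) and target coverage ≥ 0.6 (`--tcov`).
4. **reduce** — greedy clustering of calls that share an exon id;
   the best-scoring member of each cluster survives as the prediction;
   same-strand overlapping predictions are resolved by E-value.
5. Output: GFF3 + protein FASTA + codon FASTA with pipe-delimited headers
   `target|contig|strand|score|evalue|num_exons|exon-coords…`.

Internal coordinates are 0-based half-open on the plus strand; GFF3 output
is 1-based inclusive.

## CLI

```bash
# synthetic fixture: genome + truth GFF3 + diverged reference
splicecall synth --n-genes 50 --divergence 0.2 --decoys 20 --out-dir demo

# predict genes
splicecall predict demo/contigs.fasta demo/reference.fasta --out-prefix demo/run

# benchmark against the truth annotations (sensitivity, exon coverage,
# split-gene rate, optional inverted-fragment null model)
splicecall evaluate demo/contigs.fasta demo/reference.fasta \
    demo/truth.gff3 demo/true_proteins.fasta --out demo/eval.tsv --inverted-null

# taxonomy from m8 hits of predictions vs a lineage-annotated database
splicecall taxonomy hits.m8 lineages.tsv --out taxonomy.tsv
```

`--preset tara` switches to the large-scale settings (`--min-length 40`,
`--min-exon-aa 20`). Lineage TSV format: `target_id<TAB>domain;kingdom;…`.
Taxonomic ranks are truncated by prediction-target identity
(>95% species, >80 genus, >65 family, >50 order, >40 class, >30 phylum,
>20 kingdom, else domain); hits need E < 1e-5.

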