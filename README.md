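# paleodup

Tools for dissecting the duplication history of a genome against a
paleodiploid reference: synteny-block detection by anchor chaining, partition
of the blocks into two non-overlapping subgenomes, derivation of syntenic
ortholog / WGD-duplicate / tandem-paralog gene pairs, fractionation
accounting, annotation-term functional-divergence classification
(conserved / sub-functionalized / neo-functionalized), Nei–Gojobori Ka/Ks
selection analysis, and relative dating of duplication events from Ks
density peaks.

A genome-evolution simulator with full ground truth is bundled, so the whole
pipeline is exercisable end-to-end without any external downloads.

## Inputs

Per genome: gene models (GFF3, `gene` features with `ID` attributes;
`##sequence-region` directives supply chromosome lengths), coding and protein
sequences (FASTA, record ids = gene ids), a gene→term table (2-column TSV,
e.g. InterPro entry ids), plus one all-vs-all protein hit table (standard
12-column tabular format). Hits are e-value filtered (default 1e-20),
self-hits dropped, and reciprocal rows collapsed to undirected edges.

## CLI

```bash
# synthetic dataset with ground truth (GFF3/FASTA/TSV/JSON)
paleodup simulate --seed 7 --n-ref-genes 2000 --out data/

# full pipeline from one YAML config
paleodup run --config config.yaml

# individual stages
paleodup synteny --ref-gff ref.gff3 --desc-gff desc.gff3 --hits hits.tsv \
    --min-block-size 15 --max-evalue 1e-20
paleodup dup  --desc-gff desc.gff3 --hits hits.tsv --max-intervening 1
paleodup kaks --pairs pairs.tsv --cds ref.cds.fasta --cds desc.cds.fasta \
    --min-identity 0.3 --min-coverage 0.5
paleodup date --kaks kaks.tsv --ks-max 3.0 --bandwidth silverman
```

A minimal config:

```yaml
out_dir: out/
simulate:            # or an `inputs:` block with the six file paths
  seed: 7
chain:
  min_block_size: 15
  max_evalue: 1.0e-20
```

`paleodup run` writes fixed-name outputs under `out_dir`: `blocks.tsv`,
`anchors.tsv`, `pairs.tsv`, `arrays.tsv`, `kaks.tsv`, `kaks_exclusions.tsv`,
`class_comparison.tsv`, `tandem_by_chromosome.tsv`, summary tables
`table1.tsv`–`table4.tsv`, `venn.json`, `peaks.json` and `report.json`
(per-stage record counts plus a full parameter echo).

## Method notes

- The chain score is `n_anchors * match_score + gap_penalty * (rank_gap - 1)`
  per extension, with `rank_gap` the larger of the two per-genome rank gaps;
  extensions across gaps larger than `max_gap` are forbidden and chains
  shorter than `min_block_size` anchors are dropped. The decomposition is
  greedy by descending chain score and is verified against exhaustive
  monotone-chain enumeration in the tests.
- Subgenome naming is harmonized so subgenome1 carries the larger total
  anchor count; within a reference-overlap cluster blocks in one subgenome
  never overlap each other on the reference.
- Ka/Ks uses Nei–Gojobori counting (codon site fractions from the standard
  code, mutational-pathway averaging that discards pathways through stop
  codons) with Jukes–Cantor correction; proportions ≥ 3/4 are flagged
  saturated. Pairwise protein alignment is global affine-gap BLOSUM62
  (open 10, extend 0.5), back-translated onto the CDS.
- Mann–Whitney comparisons are exact by enumeration when both groups have
  ≤ 8 members, otherwise the normal approximation with tie correction.
- Tandem arrays are connected components of the same-chromosome homology
  graph at rank distance ≤ `max_intervening + 1`; an array is dated pre-WGD
  only if every member is an anchor gene of an assigned syntenic block.

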