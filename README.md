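# virtax

Comparative-genomics toolkit for collections of tailed-virus genomes:
gene-content/gene-order composite distances and two-rank taxonomic
demarcation, tail-fiber adhesin grouping linked to host-range
(efficiency-of-plating) profiles, restriction-motif frequency and
depletion analysis under a Markov null, and detection of integrated
proviruses with their attachment-site direct repeats.  A seeded
synthetic-data module generates every input the pipeline consumes, with
ground-truth labels, so all stages are testable offline.

## Layout

| module | role |
|---|---|
| `virtax.genome_io` | GenBank/FASTA I/O, naive ORF calling, proteome extraction |
| `virtax.align` | Smith–Waterman / Needleman–Wunsch protein alignment (BLOSUM62, gap 11/1), Karlin–Altschul E-values, anchored whole-genome substitution counting |
| `virtax.gene_sharing` | thresholded homology graph (>30 % identity, E < 1e-25), protein clusters, shared-gene fractions, genome signatures |
| `virtax.taxonomy` | composite generalized Jaccard distances (`1 − sqrt(J_content · J_org)`), UPGMA dendrogram, family cut at 0.8, genus assignment at >60 % shared proteins |
| `virtax.trees` | neighbor joining, outgroup rooting, identity distance matrices, single-linkage adhesin grouping |
| `virtax.host_range` | EOP normalization (isolation host = 1), log10 binning, sensitive-host profiles, the hs statistic, Mantel-style adhesin association |
| `virtax.motifs` | IUPAC motif counting (palindrome-aware, circular-aware), Markov-null expected counts, in-repo Mann–Whitney U |
| `virtax.provirus` | provirus region chaining from protein homology, att direct-repeat search, family assignment |
| `virtax.synth` | seeded generators for all of the above, with truth files |
| `virtax.cli` | `virtax` command with `simulate / classify / hostrange / motifs / provirus` subcommands |

## CLI

```bash
# generate a labelled synthetic genome collection, then classify it
virtax simulate --kind taxonomy --seed 1 --outdir sim/
virtax classify sim/genomes.gbk --outdir run/

# host-range analysis from a virus x host EOP table
virtax simulate --kind eop --seed 1 --outdir eo/
virtax hostrange --eop eo/eop.tsv --isolation eo/isolation_hosts.tsv --outdir hr/

# motif report (optionally with an MTase-status table), provirus scan
virtax motifs sim/V111.fasta --motif GATC --outdir mot/
virtax simulate --kind provirus --seed 1 --outdir pv/
virtax provirus --host pv/host.fasta --viruses pv/virus.gbk --outdir calls/
```

Every run writes a manifest (hashed inputs, full config, versions) next
to its outputs.  All thresholds default to the published demarcation
values and can be overridden via a YAML config or CLI flags.

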