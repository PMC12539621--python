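# spacerscan

Extraction, mapping and analysis of newly acquired CRISPR spacers from
noisy long-read amplicons of an expanded reporter array, plus a synthetic
amplicon simulator with planted ground truth.

The pipeline mirrors a reporter-based spacer-acquisition experiment:
amplicons spanning the leader–repeat junction of a CRISPR array are parsed
by error-tolerant repeat matching; the inter-repeat segments (new spacers)
are collapsed into a duplication tally; each unique spacer is mapped to its
protospacer locus on the chromosome or plasmid (both strands, circular
coordinates) and its PAM window is read out; downstream layers compute
hotspot bin maps, plasmid-vs-chromosome source bias with molar-excess
normalization, PAM position-frequency/information matrices, PAM-site
saturation counts, and reading-frame analytics (in-frame ATG / stop-codon
probabilities and the duplication-vs-ATG trend with a permutation test).

## Layout

| module | role |
| --- | --- |
| `spacerscan.core` | domain types, coordinate conventions, FASTA/FASTQ I/O |
| `spacerscan.align` | bit-parallel approximate matching (Myers, semi-global) |
| `spacerscan.simulate` | synthetic references, planted acquisition events, noisy reads, truth table |
| `spacerscan.parser` | read orientation, repeat finding, spacer extraction, duplicate collapse |
| `spacerscan.mapping` | spacer → protospacer assignment, PAM extraction, source classification |
| `spacerscan.analysis` | hotspot bins, bias summary, PAM matrices, motif saturation |
| `spacerscan.framestats` | closed-form frame probabilities, spacer annotation, trend test |
| `spacerscan.pipeline` / `spacerscan.cli` | orchestration, reports, command line |

Two tallying rules are deliberately separate: source **ratios** use all
spacers (duplicates retained); hotspot **maps** and **PAM matrices** use
unique spacers only.

## CLI

```sh
# simulate an amplicon pool with ground truth
spacerscan simulate --seed 1 --n-events 500 --plasmid-source-prob 0.64 \
    --outdir sim/

# full pipeline on simulated input
spacerscan run --simulate --seed 1 --n-events 500 --outdir out/

# full pipeline on real data (basecalled FASTQ + reference FASTAs)
spacerscan run --no-simulate --chromosome-fasta genome.fasta \
    --plasmid-fasta plasmid.fasta --reads-fastq reads.fastq --outdir out/

# analytic reading-frame constants
spacerscan constants --k 10
```

Outputs land in the chosen directory: `spacers.tsv`, `tally.tsv`,
`hits.tsv` (BED-like, 0-based half-open), `bins_chromosome.tsv` /
`bins_plasmid.tsv`, `pam_matrix.tsv`, `frame_annotations.tsv`,
`duplication_bins.tsv`, `bias_summary.json` and `summary.json` (counters,
thresholds, analytic constants, timings).  Exit codes: 2 invalid config,
3 missing input, 4 no spacers extracted.

## Conventions

- Coordinates 0-based, half-open, forward strand + explicit strand field.
- Chromosome and plasmid treated as circular; matching wraps the origin.
- PAM window default: 2 bases upstream of the protospacer + its first base
  (5'→3' on the protospacer strand); offsets/width configurable.
- N allowed in reads only; never matches in comparisons.
- Repeat/anchor matching tolerance `max_edit_fraction` defaults to 0.2;
  spacer mapping allows `max_edits` = 2.
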