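# riboclip

Analysis toolkit for dual-species spike-in ribosome profiling, PAR-CLIP
quantification on a collapsed multicopy reference, and gradient/blot
quantification — with synthetic-data generators that carry their ground
truth, so every stage is testable without external sequencing data.

## What it does

| Module | Purpose |
| --- | --- |
| `riboclip.reference` | Genome/ORF model; masks multimapping tRNA/rRNA genes (40-bp window, both strands) and collapses each family onto an artificial chromosome with 25-N spacers; codon/window coordinate services |
| `riboclip.synthetic_data` | Footprint libraries (per-gene expression, length distribution, frame fidelity, start/codon pause multipliers, global translation factor, spike-in species), CLIP libraries (multimap classes, per-position T→C conversion, role-specific enrichment), triangular-peak gradient traces; all pure functions of (config, seed) with a serialized `SimulationTruth` |
| `riboclip.footprint_core` | ORF assignment of read 5′ ends (window −12 of start to −15 of stop, inclusive), length-specific frame offsets (`{20:0, 21:0, 22:+1, 25:0, 26:0, 28:0, 29:+1, 30:+1, 31:+1}`; 27-mers dropped), frame composition, length histograms, per-gene counts with first-8-codon exclusion |
| `riboclip.spikein_norm` | Bulk translation ratio (analysis/spike-in CDS totals), RPKM, and per-gene rescaling from an OLS fit on the top 5% of spike-in genes |
| `riboclip.positional_stats` | Metagene occupancy (≥64-read genes), start/body ratios, 26-position nucleotide-bias G-test (χ², 3 df, Bonferroni ×26), A/P/E-site codon pause scores, K-S/median-shift pause comparisons, metacodon occupancies normalized to flanking codons |
| `riboclip.clip_quant` | Fractional multimap weights `{0:0.2, 1:0.286, 3:0.5, 255:1}`, length-normalized tRNA densities with the 64-count cutoff, ≥4-fold dual-control enrichment calls, Fisher-exact region enrichment, T→C conversion profiles (≥100-coverage mask) |
| `riboclip.gradient_quant` | Riemann-sum polysome/monosome and monosome/subunit ratios with baseline rules, best 3–4-point dilution-series slopes, per-replicate median peptide ratios |
| `riboclip.pipeline` | End-to-end drivers with balanced run reports, plus a Fisher overrepresentation utility |

## CLI

```bash
# synthetic fixtures (TSV + SAM alignments, FASTA, BED, truth JSON)
riboclip simulate footprints --out fixture/ --seed 1 --factor 0.2
riboclip simulate gradient --out trace.tsv --peak 0.4 0.05 2.0 --peak 0.7 0.05 2.0

# collapsed multicopy reference from FASTA + BED
riboclip collapse --genome genome.fa --features trnas.bed --out-prefix collapsed

# footprint ingestion (counts, length histogram, frame table)
riboclip footprints --alignments fixture/cond0_rep0.tsv \
    --annotations fixture/annotations.bed --out-prefix fp

# gradient / blot quantification
riboclip gradient pm --trace trace.tsv --boundaries bounds.json
riboclip blot slope --series series.tsv

# full translatome comparison on a simulated fixture
riboclip report --fixture fixture/ --out report/
```

Alignments are accepted as SAM/BAM or as a simplified tabular format
(`read_id  chrom  strand  five_prime  length  multimap_class
is_primary  mismatches`).

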