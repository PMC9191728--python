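# sinescout

Discovery and characterization of tRNA-head SINE (short interspersed nuclear
element) families in genome assemblies, with a small-RNA (piRNA) mapping arm
and a planted-truth genome simulator for end-to-end validation.

## What it does

* **Discovery** — scans a genome for RNA-polymerase-III type-2 promoter
  structure (11-bp A box `TRGYNNARNNG` + 11-bp B box `RGTTCRANTCC`, spaced
  25–70 bp) or ingests tRNA-scanner output, extracts 1000-nt anchored
  windows, clusters them by local-alignment similarity (≥90 % identity over
  ≥150 bp, anchor shift ≤5 nt, ≥3 members), calls element boundaries from a
  conservation profile refined by cross-member target-site-duplication
  votes, and emits majority-rule consensus models with the measured
  TSS-to-A-box offset.
* **Annotation** — enumerates full-length genomic copies of each family at
  80 %/90 % identity (12-mer seeded, semi-global verification), computes age
  profiles (n90/n80), detects 10–15-bp target site duplications, classifies
  poly(A)/microsatellite tails, and flags head-to-tail dimeric composites.
* **Small-RNA arm** — filters reads to 26–31 nt, builds a tRNA-head-masked
  copy database, maps reads with zero mismatches on both strands, restricts
  to density-called clusters, selects the SINE-related pool, and produces
  per-gene intron-level strand-split count tables and per-consensus
  coverage tracks.
* **Simulator** — plants families with exact promoter anatomy (element 5'
  end 11 bp upstream of the A box), graded copy divergence, duplicated
  10–15-bp target sites, intronic insertions into 4-exon gene models, and
  sine/background/tRNA-decoy small-RNA reads, all recorded in a ground-truth
  manifest.

## CLI

```bash
sinescout simulate --seed 5 --out sim/             # synthetic data + truth
sinescout discover --genome sim/genome.fasta --out disc/
sinescout annotate --genome sim/genome.fasta --consensus disc/consensus.fasta --out ann/
sinescout smallrna --genome sim/genome.fasta --consensus disc/consensus.fasta \
                   --genes sim/genes.gff3 --reads sim/reads.fasta --out srna/
sinescout all --config run.yaml --out out/         # discover -> annotate -> smallrna
```

All stages accept a YAML config (`genome:`, `trnascan:`, `genes:`, `reads:`,
plus `discovery:`/`annotate:`/`smallrna:`/`simulate:` parameter blocks) and
write a `run_summary.json` with per-stage counts. Internal coordinates are
0-based half-open; GFF3 and tabular reports are emitted 1-based inclusive,
BED 0-based half-open (each output file states its convention).

## Layout

```
src/sinescout/
  seqcore_io.py   FASTA/BED I/O, intervals, degenerate motifs, alignment
  promoter.py     A/B-box scanning, tRNA-scan ingestion, TSS offset
  discovery.py    windows -> clusters -> boundaries -> consensus models
  annotate.py     copy scan, age profiles, TSDs, tails, dimers
  smallrna.py     read filtering, masked copy DB, exact mapping, counting
  synth.py        planted-truth genome/gene/read simulator
  cli.py          click-based pipeline driver
tests/            pytest suite; oracles.py holds independent DP oracles;
                  test_acceptance.py implements the acceptance criteria
```

Alignment scoring defaults to match +1 / mismatch −1 / linear gap −2;
percent identity is matches over alignment columns including internal gaps.
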