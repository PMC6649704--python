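# irphase

Analysis of perfect inverted repeats embedded in mitochondrial protein-coding
sequences: detection, reading-frame phase classification, genetic-code
constraint metrics, codon-shuffle null models, and per-phase codon-usage
statistics.

## The problem

Inverted repeats — two DNA segments on the same strand where one is the exact
reverse complement of the other — fold into hairpins and are normally confined
to non-coding DNA. In some AT-rich invertebrate mitochondrial genomes
(horsehair worms are the extreme case) long perfect inverted repeats sit
*inside* functional protein-coding genes, so both arms of the hairpin encode
conserved protein sequence. `irphase` is a toolkit for characterizing this
phenomenon in any annotated mitochondrial genome:

* **Detection.** Maximal perfect inverted repeats within each CDS (an
  anti-diagonal scan of the self-complementarity matrix), plus a scored
  local-alignment detector (match +3, mismatch −4, gap −12, reporting
  threshold 15) for imperfect, decaying stems.
* **Phase.** For an in-frame repeat, exactly one codon position *k* pairs
  with itself across the arms: phase 1 pairs (1,1), (2,3), (3,2); phase 2
  pairs (2,2), (1,3), (3,1); phase 3 pairs (3,3), (1,2), (2,1). With c_A the
  codon position of the first base of the 5′ arm and c_B that of the last
  base of the 3′ arm, the phase is the unique *k* with 2k ≡ c_A + c_B (mod 3).
* **Constraint calculus.** For a fixed dipeptide on one arm, how many amino
  acids can the complementary arm's reading frame encode, and with what
  Shannon entropy, given synonymous codon freedom? Phase 3 ties first and
  second codon positions across arms and is the strictest; phase 1 ties the
  second to the degenerate third position and is the weakest. Means are
  weighted by observed dipeptide frequencies.
* **Null models.** Codon shuffling (a uniform permutation of each CDS's
  codons, preserving codon frequencies) and nucleotide shuffling, with
  replicate ensembles for repeat-count over-representation ratios and null
  phase-proportion curves.
* **Region statistics.** Wright's effective number of codons (Nc) for
  phase-1/2/3 repeat regions versus non-repeat regions, and per-amino-acid
  Fisher exact composition tests with Bonferroni correction (p < 0.05/20).
* **Synthetic data.** A generator for AT-rich coding sequences with embedded
  repeats of controlled phase/arm/loop geometry and truth tables, so every
  stage is testable without downloads.

Default genetic code is NCBI translation table 5 (invertebrate mitochondrial:
ATA→Met, AGA/AGG→Ser, TGA→Trp; stops TAA/TAG); tables 1, 2 and 4 are
available for survey work.

## Worked example

```python
from irphase import (
    GeneticCode, SynthSpec, RepeatSpec, generate_genome_set, scan_cds_set,
    phase_census, codon_usage, dipeptide_frequencies, constraint_table,
)

code = GeneticCode.from_ncbi(5)
spec = SynthSpec(
    species="demo",
    embedded_repeats=[
        RepeatSpec("nad1", phase=1, arm_len=40, loop_len=30),
        RepeatSpec("nad2", phase=2, arm_len=25, loop_len=37),
        RepeatSpec("nad5", phase=3, arm_len=20, loop_len=10),
    ],
    seed=11,
)
records, truth = generate_genome_set(spec)
scan = scan_cds_set(records, min_arm=15)
phased = [p for ps in scan.values() for p in ps]
for p in sorted(phased, key=lambda p: -p.arm_len):
    r = p.base
    print(f"{p.cds.gene}: arm {r.arm_len} bp, loop {r.loop_len} bp, "
          f"phase {p.phase}, midpoint {r.midpoint}")

usage = codon_usage(records, code)
dipeps = dipeptide_frequencies(records, code)
for ph, row in constraint_table(dipeps, code, usage).items():
    print(f"phase {ph}: mean permitted aa {row.mean_permitted_aa:.2f}, "
          f"entropy {row.mean_entropy_actual:.2f} bits "
          f"(equal codon freqs {row.mean_entropy_equal:.2f})")
```

prints

```
nad1: arm 41 bp, loop 28 bp, phase 1, midpoint 473.0
nad2: arm 26 bp, loop 37 bp, phase 2, midpoint 613.5
nad5: arm 20 bp, loop 10 bp, phase 3, midpoint 301.0
phase 1: mean permitted aa 3.50, entropy 1.45 bits (equal codon freqs 1.58)
phase 2: mean permitted aa 3.02, entropy 1.28 bits (equal codon freqs 1.42)
phase 3: mean permitted aa 1.51, entropy 0.47 bits (equal codon freqs 0.46)
```

All three embedded repeats are recovered with their requested phases (the
nad1 arm extends by one base because detection reports *maximal* repeats),
and the constraint table shows the expected strictness ordering: the
complementary arm of a phase-3 repeat can encode on average only ~1.5 amino
acids per dipeptide, against ~3.5 for phase 1.

The same analyses run from the shell on GenBank or FASTA + gene-table input:

```sh
irphase scan --genbank mygenome.gb --min-arm 15 --out results/
irphase table1 --genbank mygenome.gb --out results/table1.tsv
irphase nullrun --genbank mygenome.gb --replicates 10 --seed 1 --out results/null.json
```

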