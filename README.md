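# mulescan

Discovery and characterization of *Mutator*-like transposable elements
(MULEs) in genome assemblies, plus the statistics of a yeast
transposition assay — as a tested, reusable pipeline.

MULEs are class 2 ("cut and paste") DNA transposons with long terminal
inverted repeats (TIRs, often >100 bp) and an 8–10 bp target site
duplication (TSD) created on insertion. An autonomous element encodes a
transposase whose catalytic core is the acidic DDE triad; nonautonomous
derivatives keep the termini but carry arbitrary internal sequence,
sometimes captured host-gene fragments (Pack-MULEs). `mulescan` covers
the full computational arc of a MULE study:

- **homology search** — six-frame translated Smith–Waterman scan of a
  genome for the DDE domain, with a Karlin–Altschul surrogate E-value
  (`E = K·m·n·e^{−λS}`, gapped BLOSUM62 constants λ = 0.267, K = 0.041)
  and greedy reciprocal-overlap deduplication;
- **element annotation** — boundary detection from paired copies, TIR
  detection by anchored extension alignment, exact-match TSD calling
  (longest k ∈ [8, 10] with the k-suffix of the left flank equal to the
  k-prefix of the right flank), subterminal tandem-repeat chaining,
  terminal 10-bp palindrome pairing profile, and location of the coding
  span containing the DDE triad;
- **families and phylogeny** — single-linkage clustering at >95%
  pairwise identity, center-star multiple alignment, Saitou–Nei
  neighbor joining with deterministic tie-breaks, and column-resampling
  bootstrap supports;
- **derivative census** — mismatch-bounded seed-and-extend search for
  the element's 50-bp termini, convergent end pairing, TSD verification
  on 100-bp flanks, and Pack-MULE content classification;
- **insertion statistics** — genic-proximity classification
  (gene body / within a window / distal), a randomized genomic null
  (uniform over total genome length, 1,000 replicates) with z-scores,
  and position-frequency matrices with per-position information
  content;
- **assay analytics** — excision frequencies from colony counts,
  reintegration ratios, binomial proportions, excision-footprint
  classification (precise / flank deletion / insertion / TIR remnant /
  complex), transposon-display read mapping and reinsertion-TSD
  extraction;
- **synthetic data** — a generator that plants elements with exactly
  this structure (and a machine-readable truth table) into uniform
  random background, so every stage can be validated closed-loop.

## Worked example

Simulate a genome with planted elements, then rediscover them:

```bash
mulescan simulate --out-dir sim --seed 3 --scaffolds 2 \
    --scaffold-len 60000 --full-copies 3 --derivatives 3
# wrote genome (133601 bp), 4 genes, 6 planted elements to sim
```

The genome is larger than 2 × 60 kb because every insertion adds the
element plus its duplicated target site. Searching it with a DDE-domain
peptide query (`mulescan search --genome sim/genome.fa --query dde.faa
--post-filter 1e-15`) prints one hit per planted autonomous copy:

```
scaffold  start  end    strand  frame  score  evalue
scf1      29189  29972  +       2      1531   4.2e-172
scf2      9060   9843   +       0      1531   4.2e-172
scf2      51776  52559  +       2      1531   4.2e-172
```

Each hit is the genomic span of the catalytic domain; the score is in
BLOSUM62 units and the E-value is the deterministic surrogate, far
below any reasonable cutoff for exact copies. The derivative census
from the element's 50-bp termini verifies all six planted elements by
their perfect TSDs, split by duplication length:

```bash
mulescan derivatives --genome sim/genome.fa --termini term.fa
# {"candidates": 6, "tsd_verified": 6, "tsd8": 5, "tsd9": 1, "pack": 0}
```

Assay arithmetic works directly from colony counts — 244 revertant
colonies over a culture whose viable count was 20 colonies from 100 µl
of a 10⁵ dilution (≈10⁷ viable cells):

```bash
mulescan assay rates --revertants 244 --dilution 1e5:20
# {"viable_cells": 10000000.0, "frequency": 2.44e-05}
```

i.e. an excision frequency of 2.44 × 10⁻⁵ events per viable cell.

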