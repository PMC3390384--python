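# pangrep

Comparative-genomics toolkit for multi-strain bacterial genome sets, built
around the analyses typical of *Pseudomonas fluorescens*-group studies:

* **Pan-genome set algebra** — best-match protein orthology, a
  presence/absence matrix, and core / pan / strain-unique / clade-specific
  gene sets, Venn partitions and pairwise shared-gene proportions;
* **REP element landscapes** — de-novo mining of repetitive extragenic
  palindromic (REP) repeat families, consensus scanning, REPIN pair spacing,
  REP desert calling, and REP-associated tyrosine transposase (RAYT)
  flanking analysis;
* **Compositional atypicality** — sliding-window trinucleotide chi-square
  tracks and GC skew, flagging candidate horizontally acquired regions;
* **T3SS effector screening** — Hrp-box promoter-motif scanning combined
  with N-terminal amino-acid composition rules.

Because such analyses are usually validated only by eye, the package ships a
first-class **synthetic genome generator** that plants every structure the
pipeline looks for — ortholog families under a controlled divergence model,
REP copies and oppositely oriented pairs at fixed spacing, REP-free desert
blocks with shifted composition, REP-flanked RAYT genes, and effector genes
with planted promoter motifs — together with machine-readable ground truth,
so every stage is tested by exact recovery rather than inspection.

It is aimed at microbial comparative genomicists who want the bespoke
"methods section" computations of strain-panel papers as a reusable, tested
library.

## The core computations

**Orthology.** For strains $A \ne B$, every protein of $A$ is locally
aligned (Smith–Waterman, BLOSUM62, gap open 11 / extend 1) against the
proteome of $B$; E-values follow Karlin–Altschul,
$E = K m n\, e^{-\lambda S}$ with $K = 0.041$, $\lambda = 0.267$, query
length $m$ and database residue count $n$. Per query, the best subject with
$E \le 10^{-5}$ is kept; gene families are connected components of the
reciprocal-best-hit graph (a unidirectional mode is available). Core genes
are families present in every strain; the pan-genome is the union; the
shared proportion of two strains divides their shared family count by the
smaller strain's family count.

**REP landscape.** Repeat families are motifs $>30$ nt occurring more than
10 times per genome, discovered by exact k-mer seeding and greedy gapless
extension under a 10% per-copy mismatch budget. Each genome is rescanned
with the family consensus at $\ge 90\%$ ungapped identity on both strands; a
family with $\ge 250$ intergenic copies is *primary* for that genome.
Center-adjacent copies closer than 200 bp form pairs whose spacing histogram
exposes the REPIN doublet mode (typically 60–70 bp, oppositely oriented).
Maximal copy-free intervals $\ge 25$ kb are REP deserts. A RAYT gene is
REP-flanked when a copy center lies within 300 bp of both gene edges.

**Composition.** Windows (default 5 kb, step 1 kb) are scored with a
normalized Pearson chi-square of their 64 overlapping-trinucleotide counts
against the genome background; contiguous windows above a robust
(median/MAD) null quantile merge into candidate atypical regions. GC skew is
$(G-C)/(G+C)$ per window.

**Effector screen.** Candidates need a promoter-motif hit (user-supplied
position weight matrix, log-odds scored over the strand-aware upstream
window) *and* an N-terminus passing four rules: Ser fraction $\ge 0.10$ and
polar fraction $\ge 0.40$ over the first 50 aa, at most one acidic residue
(D/E) in the first 12 positions, and an aliphatic residue (A/V/L/I) at
position 3 or 4.

## Worked example

```bash
pangrep -v run-all --seed 1 --outdir demo
```

simulates the default four-strain dataset (two clades, 120 core families,
15 clade families per clade, 25 unique genes per strain plus RAYT and
effector accessory genes, 300 REP copies per strain of a 35-nt imperfect
palindrome, a 30-kb composition-shifted desert) and runs every stage:

```
INFO stage=io strains=4 genome_bp={'s1': 222537, 's2': 220670, 's3': 222884, 's4': 222934}
INFO stage=orthology families=282
INFO stage=pangenome core=120 pan=282
INFO stage=rep families={'s1': 1, 's2': 1, 's3': 1, 's4': 1} deserts=4
INFO stage=composition regions=15
INFO stage=effectors candidates={'s1': 2, 's2': 2, 's3': 2, 's4': 2}
```

The orthology layer recovers exactly the 282 planted families (120 core +
30 clade + 100 unique + 32 accessory), so `pangenome/sets.tsv` reports the
planted design verbatim:

```
label    n_families  genes_s1  genes_s2  genes_s3  genes_s4
core     120         120       120       120       120
pan      282         168       168       168       168
unique:s1 33         33        0         0         0
```

One REP family is mined per strain, its consensus equal to the planted
35-mer, with 302 intergenic copies (300 configured + 2 RAYT flanks), hence
primary under the 250-copy rule; the spacing histogram has its mode at the
planted 65 bp:

```
strain  family_id  consensus                            length  copies  intergenic_copies  primary
s1      rep1       GTAGGAGCGAGTTCAACTGGCAATCTCGCTCCTAC  35      302     302                1
```

`rep/deserts.bed` contains exactly the four planted REP-free intervals, and
`composition/atypical.bed` calls the planted islands (the 33-kb call below
covers the 30-kb planted block):

```
s1      101000  134000  atypical  0.15087
```

The two candidates per strain in `effectors/candidates.tsv` are exactly the
planted rule-conforming genes with promoter motifs; the decoys violating a
single rule appear in `effectors/audit.tsv` with that rule flagged false.

Per-stage subcommands (`simulate`, `orthology`, `pangenome`, `rep`,
`composition`, `effectors`) accept the same `--config/--seed/--outdir`
options; a YAML config can override any generator or analysis parameter.

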