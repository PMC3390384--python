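# Methods

This note documents the models, decision rules and numerical choices behind
`pangrep`, the assumptions of its synthetic benchmark, and what the passing
tests do and do not demonstrate about real data.

## Coordinates and formats

All internal coordinates are 0-based half-open; GFF3's 1-based inclusive
convention is converted at the I/O boundary and nowhere else. CDS intervals
exclude the stop codon, so a translation always has length
`(end - start) / 3`. Genomes are linear; features may not wrap an origin.
`N` never matches any base during mining or scanning — conservative for
draft assemblies, where runs of `N` would otherwise seed spurious repeats.

## Orthology layer

The built-in similarity search is a desk-scale analogue of all-vs-all
BLASTp: exact 4-mer seeding selects candidate pairs, which are scored by
Smith–Waterman local alignment (BLOSUM62, gap open 11 / extend 1, via
Biopython's PairwiseAligner). E-values use the Karlin–Altschul form
`E = K·m·n·exp(-λS)` with `K = 0.041`, `λ = 0.267`, query length `m` and —
following the BLAST database convention — the subject proteome's total
residue count as `n`. Two approximations are deliberate and documented:
the constants are applied to gapped scores without edge-effect or
composition corrections, and seeding can in principle miss a significant
hit with no exact shared 4-mer (irrelevant above ~30% identity at realistic
lengths; the test suite checks equivalence against exhaustive all-pairs
alignment). The database-size convention matters: with per-pair `n`, a
four-strain set of ~670 proteins is *expected* to contain one or two random
cross-strain alignments under E = 1e-5, which would contaminate every
downstream set statistic.

Best matches keep, per query, the subject with maximal bitscore among hits
with `E <= 1e-5` (ties: lower E-value, then lexicographically smaller
subject id — an arbitrary but deterministic rule). Families are connected
components of the best-hit graph. The default requires reciprocity, which
is the safer behaviour around paralogs; a unidirectional mode mirrors the
looser "best match" reading and is exposed as a config switch. Component
assembly can chain A–B–C without a direct A–C edge; this is accepted
multiway semantics, not a bug. Within-strain duplicates are never linked
directly: a paralog enters a family only via a reciprocal cross-strain
edge, and the unchosen copy remains a singleton.

Set-algebra counts are reported in *families*, with per-strain gene counts
alongside, because family counts and CDS counts diverge in the presence of
paralogs. The pairwise shared proportion divides shared-family counts by
the smaller strain's family count by default; a `cds` denominator variant
uses raw gene counts (identical when paralog-free).

## REP landscape

Thresholds follow the field's printed conventions: repeat families are
motifs > 30 nt occurring more than 10 times in a genome; scanning accepts
windows at >= 90% ungapped identity to the consensus; a family with >= 250
intergenic copies in a genome is *primary* there; adjacent copies pair when
their centers are < 200 bp apart; REP deserts are copy-free intervals
>= 25 kb.

The discovery algorithm itself is this package's own (a lightweight
stand-in for de-novo repeat finders): canonicalised exact 15-mers occurring
>= 11 times seed a gapless multiple alignment of their loci, extended one
column at a time in both directions. A copy is dropped once its mismatches
against the running column majority exceed 10% of the current length, and a
direction stops extending when fewer than 11 copies would survive **or**
when the majority base falls below 70% support. The second condition is
essential: without it the extension walks into random flanking sequence,
keeping whichever ~11 copies happen to agree and destroying the consensus.
At <= 10% per-copy divergence true columns have ~90%+ support while random
columns sit near 25–30%, so 0.7 separates the regimes with wide margins.
Regions claimed by a mined family are not re-seeded, and near-duplicate
consensi (>= 90% sliding identity, either strand) are merged. The mined
consensus orientation is arbitrary (canonical k-mers see both strands);
downstream comparisons treat a consensus and its reverse complement as the
same motif.

Scanning is ungapped identity against the consensus on both strands, not a
profile HMM: deterministic, dependency-free, and exactly the ">= 90%"
rule. Overlapping reports on one strand collapse to the best-identity
window. Desert gaps are measured edge-to-edge (occurrence end to next
start) by default with a center-to-center option; genome ends count as
desert boundaries, and an occurrence-free genome is one desert. Pairing
considers consecutive-by-center copies only (an "adjacent pairs" reading),
with the spacing histogram in 1-bp bins and the modal bin reported. RAYT
flanking uses a 300-bp window on both gene edges — the field does not
quantify "flanked", so the window is a config parameter.

## Compositional atypicality

The window score is a normalized Pearson chi-square: with overlapping
trinucleotide counts `c_t` (N-containing triplets dropped), total `n_w`,
and smoothed genome-wide background frequencies `p_t`,
`score = (1/n_w) Σ_t (c_t − n_w p_t)² / (n_w p_t)`. For homogeneous
multinomial windows the unnormalized statistic is ~χ²(63), so the null
mean is 63/n_w — verified by simulation in the tests. On assembled genomes,
however, every window mixes coding and intergenic composition and the
overlapping triplets are dependent, which inflates all scores well above
the theoretical null. Region calling therefore thresholds at a *robust
empirical* null by default: median + z·1.4826·MAD of the observed scores,
with z the normal quantile of the `percentile` parameter (default 99).
Median and MAD ignore a minority of hot windows, so a large contiguous
island is called in full — a literal 99th-percentile cut would truncate a
30-kb island to its hottest 1% of windows. The literal empirical percentile
and the χ²(63) quantile remain available as modes. Counting is
forward-strand by default with no strand symmetrization (a symmetrized
convention exists in the literature; mixing the two silently would be
worse than picking one). This scorer is a self-contained implementation of
the *concept* of trinucleotide atypicality and is validated only against
synthetic ground truth; no numeric agreement with any particular published
track is claimed.

GC skew is `(G−C)/(G+C)` per window, defined as 0 when a window has no G
or C.

## Effector screen

The N-terminal filter evaluates four rules on each translation: Ser
fraction and polar-residue fraction (polar set S,T,N,Q,C,Y) over the first
50 aa, at most one acidic residue (D,E) within the first 12 positions, and
an aliphatic residue (A,V,L,I) at position 3 or 4, numbering 1-based from
the initiator Met. The positional and acidic rules are taken as printed;
"abundance of Ser and polar residues" is unquantified in the literature, so
the thresholds (Ser >= 10%, polar >= 40%) are this package's configurable
defaults, not published values. Sequences shorter than 12 aa get an
explicit not-screenable status. The promoter side scans the strand-aware
upstream window (default 500 bp) with a log-odds position weight matrix
against a uniform background; the PWM is user input — no default Hrp-box
model is shipped, since fabricating one would imply a provenance it does
not have. A reported offset is the distance from motif start to the start
codon in gene orientation. Candidates must pass all four rules *and* carry
a promoter hit; a rules-only mode drops the promoter requirement, and the
full per-gene audit table always records which rule failed.

## Synthetic data generator

The generator is the package's measurement instrument; its defaults are the
study conditions under which all recovery claims are made: 4 strains in two
clades, 120 core families, 15 families per clade, 25 unique genes per
strain, divergence 0.1, proteins 100–200 aa; 300 REP copies per strain of a
35-nt imperfect palindrome with at most 2 mutations per copy (identity
>= 0.94), 60% of copies in oppositely oriented pairs at 65 bp
center-to-center spacing; one 30-kb desert block at total-variation shift
0.35; one RAYT per strain with a REP copy within 300 bp of each flank; and
per strain two conforming effector genes, four single-rule decoys and one
motif-less conforming control, with the motif planted 120 bp upstream.

Protein families evolve under i.i.d. uniform amino-acid substitution from a
per-family ancestor, no indels. `divergence` is defined as the expected
*pairwise* between-strain difference: each copy mutates at per-site rate
`r = (19/20)(1 − sqrt(1 − (360/361)d))`, giving expected pairwise identity
exactly `1 − 18d/19` (0.905 at d = 0.1) — closed form, so the tests assert
it to Monte-Carlo error. Unique families are drawn independently; two
random proteins share ~5% identity, far below any ortholog threshold.

Genes are reverse-translated with one fixed codon per amino acid (uniform
synonymous choice is available), which keeps the nucleotide background
composition controlled for the atypicality module; synthetic CDSs therefore
need not start with ATG, which no analysis here depends on. Intergenic
background is i.i.d. with base probabilities (A,C,G,T) = (.20,.30,.30,.20).
REP copies and pairs are placed only in intergenic gaps, spaced >= 250 bp
between insertion sites so planted pairs are the only sub-200-bp
adjacencies and the histogram mode is unambiguous. Desert blocks sample
i.i.d. trinucleotides from a distribution at an exact total-variation
distance from the background (linear blend toward mass on the 32
least-likely trinucleotides), are REP-free by construction, and double as
the planted atypical islands. Because genes and REP sites keep all other
inter-copy gaps far below 25 kb, the recorded desert truth (the maximal
copy-free interval around each block) is recovered exactly by the caller.

The default consensus `GTAGGAGCGAG·TTCAACTGGCAAT·CTCGCTCCTAC` has 11-nt
perfect palindromic arms around an asymmetric core, so its reverse
complement is only ~74% self-identical: plus- and minus-strand scans cannot
double-report one locus, which keeps planted strand assignments and scan
precision well defined.

What the generator does **not** emulate — indels, recombination,
phylogenetic correlation between strains, codon-usage bias, repeat-family
mixtures, assembly gaps — bounds what the passing tests show: they certify
the algebra, the decision rules and the detection machinery against a
clean, fully specified model of the relevant structures, not performance on
real draft assemblies.

## Pipeline and determinism

One top-level seed fans out to per-stage child seeds via
`numpy.random.SeedSequence`, so stage order and stage selection cannot
perturb another stage's randomness; two identically configured runs produce
byte-identical output bundles, verified by sha256 in the manifest. Config
files are validated strictly (any unknown key aborts before compute), and a
stage failure aborts the run with the stage named. Default problem sizes
(four ~220-kb genomes, ~170 proteins per strain) were chosen so a full
run-all completes in well under a minute on one CPU while keeping every
planted count large enough for stable statistics (e.g. 360 pairs behind
the spacing mode, ~1200 REP copies behind scan recall).

## Known limitations

* E-values are approximate; ingested real BLAST tables take precedence over
  the internal search when both are available, and the same cutoff applies.
* Gapless mining cannot model repeats with internal indel polymorphism; a
  diverged copy with an indel is found by the scanner only if one gapless
  register still reaches 90% identity.
* The atypicality scorer's absolute values depend on window size and the
  coding/intergenic mixture; only relative calls within one genome are
  meaningful.
* Circular genomes are handled as linear; features and intervals may not
  span the origin, and window tracks have edge effects at both ends.
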