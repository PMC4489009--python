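# Methods

## Scope and data model

`gliadinkit` annotates cloned gliadin coding sequences (CDS, FASTA) and
their companion tables: a gene catalogue (gene, GenBank id, cDNA
evidence, draft-genome id, fragment length, predicted amino-acid length
or a `pseudo` flag, cysteine count), per-gene per-sample uniquely-mapped
read counts with library sizes, and a 2-DE spot table (spot id, %Vol,
observed MW/pI, optional peptide lists).  Coordinates are 1-based and
inclusive: protein space for domains/epitopes/cysteines, CDS base pairs
for nucleotide events.  The CDS convention excludes the terminal stop
codon (a full-ORF fragment of 3N bp encodes N residues); trailing stops
are trimmed with a warning.

One published catalogue row (Gli-α-13: 864 bp, 287 aa) violates the
3 bp-per-residue arithmetic; the parser therefore *flags* rather than
rejects inconsistent full-ORF rows (`GeneTableRow.length_consistent`).

## ORF status and stop-codon origin

A gene is `full_orf` when its in-frame translation has no internal stop
and no frame-breaking indel is found; `pseudo_frameshift` when an indel
of length ≢ 0 (mod 3) is detected against its reference; otherwise any
internal stop makes it `pseudo_stop`.

The reference for each pseudogene is the panel member (full-ORF genes of
the family) with the highest global nucleotide identity — computed with
edlib edit distance — with ties broken by reference length, then id.
Detailed alignment uses a global pairwise aligner with match +1,
mismatch −1, gap open −5, gap extend −1 (all overridable).  Each stop
codon is mapped through the alignment to its reference codon; the origin
is labelled `CAA->TAA`, `CAG->TAG` or `CGA->TGA` exactly when a single
C→T at codon position 1 explains the observation, `frameshift-induced`
when the mapped reference codon is gapped, `unexplained` otherwise.
Indel positions are reported at the first affected reference base and
left-normalized (shifted to the leftmost equivalent placement), the
usual convention inside repeat runs; without this, positions inside
CAA/CAG homopolymer context would be alignment-ambiguous.

## Domain grammar

Signal peptides are fixed per-type lengths (α: 20, γ: 20, ω: 19
residues; configurable, optionally per gene) rather than predicted
cleavage sites — deterministic and testable, at the cost of per-gene
cleavage variation.

PolyQ tracts are maximal stretches ≥ 6 residues, ≥ 80% Q, starting and
ending with Q; Q runs separated by ≤ 2 residues merge when the merged
stretch keeps the Q fraction, so a single substituted residue (the Q→A
and Q→K markers of the α groups) does not split a tract.  In α proteins
the first tract of the mature chain is QI and the second QII (leftmost
wins ties, as QI precedes QII); fewer than two tracts yields an empty
QII plus a warning rather than an error.  γ domain II is the largest
region covered ≥ 60% by PFPQ₁₋₂(PQQ)₁₋₂ unit matches, domain IV the
longest tract after it; the ω repetitive region is the analogous
unit-covered span for PFPQPQQ/PFPQQPQQ/QQQP.  Every segmentation is a
partition: the ordered labels are fixed per type, empty segments are
permitted, and segment lengths always sum to the protein length.

Type inference scores cysteine count (0 → ω candidate, 5–7 → α, 8 → γ),
paired polyQ tracts (α), γ repeat units and ω unit content; `unknown` is
returned below threshold or on ties.

## Epitopes, motifs, classes

Epitope scanning is exact substring matching (the "100% match"
convention of peptide-to-sequence assignment), overlapping occurrences
included; epitopes sharing a sequence (γ4c/DQ8-glia-γ1a, γ3/DQ8-glia-γ1b,
γ1/DQ8.5-glia-γ1) produce one hit carrying all names, since the
distinction is deamidation context, not sequence.  A hit's domain is the
domain containing its start residue.  The shipped library includes both
published spellings of the immunoreactive ω hexapeptide (QQPPQQ and
QQFPQQ) under distinct names, as the sources disagree.  Near-miss
reports enumerate windows at Hamming distance exactly 1 — the
single-substitution disruptions (e.g. S for P at position 8 of
DQ2.5-glia-α2) typical of A-genome α gliadins.

Repeat units are counted greedily left-to-right without overlap by
default (tandem-unit convention); an overlapping count is available.
Q:P:F ratios are fractions among Q+P+F residues, reduced to small
integers by rounding 8× the fractions; ω types come from the first three
mature residues (ARQ/ARE → ARQ/E; KEL; SRL; TRQ), with any other start
whose composition sits within 0.05 of the canonical 4:3:1 fractions
called an ARQ/E-like variant.  α groups: I = Q→A in QI plus DQ8-glia-α1;
II = Q→K in QII plus DQ2.5-glia-α1a and -α3; III = pure tracts and 3–4
distinct α epitopes; otherwise unclassified.

## Physicochemistry

MW is the sum of average residue masses plus one water (18.0153 Da) —
the gel-scale quantity spot tables print; monoisotopic peptide masses
(for digests) come from pyteomics.  pI is the root of the
Henderson–Hasselbalch net charge (N-terminus, K, R, H positive;
C-terminus, D, E, C, Y negative), found by bisection on [0, 14] to
0.005 pH; the charge is strictly decreasing in pH so the root is unique.
pKa sets: Bjellqvist (default) and EMBOSS; the set name is recorded in
every output row because published pI values rarely state theirs, and
exact reproduction of printed pI values is deliberately not promised.
MW/pI default to the full predicted chain (printed MW magnitudes match
full-length chains); a mature-chain option removes the signal peptide.

## Expression

RPKM = C·10⁹/(N·L) with L the cloned fragment length and N the
per-sample library size; replicates are averaged to stage means before
any thresholding (median available).  A gene is *expressed* when any
grain-stage mean exceeds the threshold (default 1000 RPKM); leaf samples
are excluded so the call is an endosperm criterion.  A profile is
*stable* when the 10- and 20-DPA means both exceed 70% of the 15-DPA
value.  Both constants are config keys.  Read alignment is out of scope;
the module ingests count tables.

## Proteomics

Chymotryptic digestion cleaves C-terminal to F, Y, W, L and M except
before proline (the extended specificity that gliadin peptide data
require; a strict F/Y/W rule is switchable), with 0–2 missed cleavages
and a minimum length of 5 by default.  A spot is uniquely assigned when
exactly one gene owns a peptide found in no other protein; several genes
with exclusive peptides mark a mixture; all-shared peptides leave the
intersection-supported group.  Ambiguous volume is never split
fractionally among genes — group totals are reported, and one gene may
own several spots (the model does not attempt to explain multi-spot
genes).  Spectral scoring, mass tolerances and search-engine
significance are not re-implemented; matching is sequence-level.

## Synthetic families

Genes are built codon by codon, domain by domain, so nucleotide events
are physically plantable: polyQ codons are CAA/CAG draws (60/40),
arginines occasionally CGA, and pseudogenization is a real C→T at a
planted codon or a real single-base deletion.  Defaults emulate the
study conditions of a diploid-wheat family survey: 23 α + 3 γ + 2 ω
genes, pseudogene fraction 12/28, 1–3 stops per pseudogene with a rare
CGA→TGA origin and a ~1/12 frameshift route, QI tracts of 9–33 residues
(27–99 bp), α cysteines 4+2 in UI/UII, γ 6+2 in III/V, ω none; stage
multipliers silent at 5 DPA, peak at 15 DPA, decline to 25 DPA, leaf at
background, three replicates of ~21.8 M reads, negative-binomial counts
(dispersion 0.05) around peak RPKM drawn log-normally (median 15 000,
σ = 0.6, clipped to 3 000–40 000 so every active gene clears the
expressed threshold and library sizes are never exceeded); spots derive
from each active protein's MW/pI with small jitter, near-identical
proteins (protein identity ≥ 0.96) merging into one ambiguous spot whose
peptides are drawn from the shared digest.

Design choices worth knowing:

- *Pseudogenes are mutated near-copies of an active family member*
  (synonymous-only divergence, 5 codons), mirroring their structural
  similarity to full-ORF genes at the same loci and making exact
  stop-origin recovery well-posed.  PolyQ lengths are not varied in the
  copies: a length change inside a homopolymer makes gap placement, and
  hence the origin call, inherently ambiguous.
- *Template SNPs*: each active gene receives a few benign substitutions
  in its unique/template domains, as real paralogs differ by SNPs
  throughout; without them the proline-rich repeats (uncleavable by
  chymotrypsin) would leave near-paralogs peptide-indistinguishable.
- A planted DQ2.5-glia-α1a is never followed by a P-starting unit, which
  would assemble DQ2.5-glia-α2 — absent from A-genome α gliadins.
- All randomness flows from one seed through a single generator; a fixed
  seed reproduces byte-identical FASTA output.

What the generator does **not** emulate — hence what passing tests do
not show about real data: phylogenetic structure (duplication trees,
selection), read-level sequencing artifacts, intron/splice handling
(gliadin genes are intronless), post-translational modification,
gel-running nonlinearity beyond Gaussian MW/pI jitter, and genuinely
novel repeat vocabularies.  Real families will show lower boundary- and
origin-recovery rates than the synthetic ceiling.

## Problem sizes used in the test and acceptance runs

Recovery studies run on a 200-gene seeded family (ORF status, stop
origins, domain boundaries), 100 seeded expression designs of 28 genes
(expressed-set accuracy), 10 seeded spot tables (assignment round
trips), and oracle comparisons on 100 random sequences (epitope
scanner), 50 random proteins (digestion) and 20 proteins (pI grid
search, 0.001-pH step).  These sizes are the package's chosen reporting
scale; all complete in well under a minute on one CPU.

## Known limitations

- Signal-peptide lengths are fixed per type, not predicted; per-gene
  overrides are accepted but no HMM is run.
- Stop-origin calls depend on reference choice; the best-identity rule
  is a heuristic and a deeply diverged family may defeat it.
- The ×3 length check, ω typing and α grouping follow printed
  conventions; catalogues with other conventions need the config knobs.
- pI values are pKa-set-dependent; cross-study comparisons should fix
  the set explicitly.
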