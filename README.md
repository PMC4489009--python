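# gliadinkit

Annotation toolkit for **gliadin gene families** — the α-, γ- and
ω-type prolamin seed-storage proteins of wheat and its wild diploid
relatives (e.g. *Triticum urartu*, the A-genome donor).

Gliadin families are hard to annotate with generic tools: the genes are
intronless, highly similar paralogs; roughly half are pseudogenes
interrupted by internal stop codons that arise from C→T transitions at
glutamine codons (CAA→TAA, CAG→TAG, rarely CGA→TGA); their proteins are
built from a rigid domain grammar (signal peptide, repeat region,
polyglutamine tracts, cysteine-bearing unique domains); and their
medical relevance rests on exact-match celiac-disease (CD) epitope
content.  `gliadinkit` implements this domain logic end to end, for
anyone cataloguing a cloned prolamin family:

- **ORF status & mutation origin** (`orf_core`) — translation, internal
  stop detection, frameshift calling against the best full-ORF homolog,
  and classification of each stop's origin (`CAA->TAA`, `CAG->TAG`,
  `CGA->TGA`, frameshift-induced, unexplained).
- **Domain grammar** (`domain_grammar`) — α/γ/ω type inference and
  segmentation: α = signal, repetitive, QI, UI, QII, UII; γ = signal,
  I–V with PFPQ₁₋₂(PQQ)₁₋₂ repeats in domain II; ω = signal, N-terminal,
  hepta/octapeptide repeat region, C-terminal.
- **Epitopes & motifs** (`motif_epitope`) — exact-match scanning of the
  shipped CD epitope library (DQ2.5/DQ8 α, γ and ω epitopes plus the
  immunoreactive 19- and 12-residue peptides), single-substitution
  near-miss reports, cysteine skeleton profiling (6 in α, 8 in γ, 0 in
  ω), repeat-unit counts, Q:P:F ratios, ω typing (ARQ/E, KEL, SRL, TRQ)
  and α grouping (I/II/III).
- **Physicochemistry** (`physchem`) — average-mass MW and
  Henderson–Hasselbalch/bisection pI with selectable pKa sets.
- **Expression** (`expression`) — RPKM (`C·10⁹/(N·L)`) from count
  tables over a grain-development design (5–25 days post-anthesis +
  flag leaf), the >1000-RPKM expressed/silent call (endosperm criterion),
  peak stage, the 70% grain-filling stability rule and fold spreads.
- **Proteomics** (`proteomics`) — in-silico chymotryptic digestion
  (cleavage after F/Y/W/L/M, never before P), peptide-to-protein
  matching, unique-vs-ambiguous 2-DE spot assignment and percent-volume
  aggregation per gene and per class.
- **Synthetic families** (`synthetic`) — a codon-level generator with
  complete ground truth (domains, planted epitopes, stop origins,
  expression design, spot tables) so every stage is testable offline.

## Worked example

```python
from gliadinkit import pipeline
from gliadinkit.synthetic import SimConfig, generate_family

records, truth = generate_family(SimConfig(seed=1))
out = pipeline.run_annotate(records)
print(out["summary"])
```

```
{'n_genes': 28, 'n_alpha': 23, 'n_gamma': 3, 'n_omega': 2, 'n_full_orf': 15, 'n_pseudo': 13}
```

Each catalogue row carries the type, ORF status, lengths, cysteine count
and epitope hits, e.g. a pseudogene row reports its stop origins
directly: `Gli-alpha-05  pseudo_stop  ...  CAA->TAA;CAG->TAG`.  The
`examples/` scripts walk one capability each (catalogue statistics,
domain/epitope annotation, expression profiles, spot assignment) and
print what the numbers mean; the same stages are available as a thin CLI
(`gliadinkit annotate|expression|proteomics|simulate|report`).

Aggregating the bundled, transcribed 2-DE spot table of the PI428198
family reproduces its published abundance structure:

```python
from gliadinkit import proteomics, seqio
v = proteomics.aggregate_volumes(seqio.load_reference_spot_table())
v["per_gene"]["Gli-γ-1"], v["per_class"]["γ"], v["total"]
# (49.27, 53.39, 100.01)
```

i.e. the three Gli-γ-1 spots hold 49.27% of the extracted gliadin
fraction, the γ class 53.39%, and the table totals 100 within rounding.

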