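"""Celiac epitope content and domain structure of one α gliadin.

Builds an active α-gliadin gene, segments it into signal/repetitive/
QI/UI/QII/UII, scans the shipped epitope library and prints every hit
with its domain, then shows a near-miss report: windows one substitution
away from the DQ2.5-glia-α2 epitope, the disruption pattern typical of
A-genome α gliadins.
"""

import numpy as np

from gliadinkit import domain_grammar as dg
from gliadinkit import motif_epitope as me
from gliadinkit.synthetic import SimConfig, generate_family

cfg = SimConfig(seed=8, n_alpha=2, n_gamma=0, n_omega=0, pseudogene_fraction=0.0,
                n_duplicate_pairs=0)
_, truth = generate_family(cfg, np.random.default_rng(8))
gid = truth.active_ids()[0]
protein = truth.genes[gid].protein

ann = dg.segment_domains(protein, "alpha", gid)
print(f"{gid}: {len(protein)} residues")
for label, s, e in ann.domains:
    print(f"  {label:<11} {s:>4}-{e:<4} ({max(0, e - s + 1)} aa)")

hits = me.scan_epitopes(protein, annotation=ann)
print("\nepitope hits (name @ start, domain):")
for h in hits:
    print(f"  {'/'.join(h.epitope_names)} @ {h.start} in {h.domain_label}")

print("\nnear-misses of DQ2.5-glia-α2 (position, epitope pos, observed→expected):")
for start, pos, obs, exp in me.near_miss_report(protein, "PQPQLPYPQ")[:5]:
    print(f"  window @{start}: position {pos} has {obs} instead of {exp}")
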