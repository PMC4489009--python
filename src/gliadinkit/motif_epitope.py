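"""Celiac-disease epitope scanning, cysteine profiling, repeat-unit
counting, Q:P:F composition and ω/α class calls.

The epitope library ships as a versioned TSV (name, sequence, class,
notes).  Scanning is exact substring matching ("100% match"), with
overlapping occurrences reported; epitopes that share a sequence (e.g.
DQ2.5-glia-γ4c and DQ8-glia-γ1a) yield one hit carrying all names.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib.resources import files

import pandas as pd

from .domain_grammar import ProteinAnnotation

ALPHA_GROUPS = ("I", "II", "III", "unclassified")
OMEGA_TYPES = ("ARQ/E", "KEL", "SRL", "TRQ", "ARQ/E-like variant", "unknown")

#: mature-protein Q:P:F fractions typical of ARQ/E-type ω gliadins (4:3:1)
ARQE_QPF_FRACTIONS = (0.5, 0.375, 0.125)


@dataclass(frozen=True)
class EpitopeDef:
    name: str
    sequence: str
    gliadin_class: str
    notes: str = ""

    def __post_init__(self) -> None:
        if len(self.sequence) not in (4, 6, 7, 9, 12, 19):
            raise ValueError(
                f"{self.name}: unexpected epitope length {len(self.sequence)}"
            )


@dataclass
class EpitopeHit:
    epitope_names: list[str]       # all library names sharing the matched sequence
    sequence: str
    start: int                     # 1-based protein position
    domain_label: str | None = None


@dataclass
class CysteineProfile:
    total: int
    positions: list[int]                       # 1-based
    per_domain: dict[str, int] = field(default_factory=dict)
    moved_positions: list[tuple[int, int]] = field(default_factory=list)


def load_epitope_library() -> list[EpitopeDef]:
    """The shipped epitope/immunoreactive-peptide library."""
    df = pd.read_csv(files("gliadinkit.data") / "epitope_library.tsv", sep="\t")
    return [
        EpitopeDef(r["name"], r["sequence"], r["gliadin_class"], r.get("notes", ""))
        for r in df.to_dict("records")
    ]


def scan_epitopes(
    protein: str,
    library: list[EpitopeDef] | None = None,
    annotation: ProteinAnnotation | None = None,
) -> list[EpitopeHit]:
    """All exact epitope occurrences in a protein, overlapping allowed.

    A hit's domain label (when an annotation is supplied) is the domain
    containing the hit's start residue.
    """
    library = library if library is not None else load_epitope_library()
    if not library:
        raise ValueError("empty epitope library")
    seq = protein.upper()
    by_sequence: dict[str, list[str]] = {}
    for e in library:
        by_sequence.setdefault(e.sequence, []).append(e.name)
    hits: list[EpitopeHit] = []
    for motif, names in by_sequence.items():
        start = seq.find(motif)
        while start != -1:
            hits.append(
                EpitopeHit(
                    epitope_names=sorted(names),
                    sequence=motif,
                    start=start + 1,
                    domain_label=(
                        annotation.domain_of(start + 1) if annotation else None
                    ),
                )
            )
            start = seq.find(motif, start + 1)
    hits.sort(key=lambda h: (h.start, h.sequence))
    return hits


def near_miss_report(
    protein: str, epitope: EpitopeDef | str
) -> list[tuple[int, int, str, str]]:
    """Windows at Hamming distance exactly 1 from the epitope.

    Returns ``(start, position_in_epitope, observed, expected)`` with both
    coordinates 1-based; exact matches are excluded.  This is how a single
    substitution that disrupts an epitope (e.g. the S-for-P at position 8
    of DQ2.5-glia-α2 in A-genome α gliadins) is surfaced.
    """
    motif = epitope.sequence if isinstance(epitope, EpitopeDef) else epitope
    if len(motif) < 4:
        raise ValueError("epitope too short for a near-miss scan")
    seq = protein.upper()
    out = []
    for i in range(len(seq) - len(motif) + 1):
        window = seq[i : i + len(motif)]
        mismatches = [j for j, (a, b) in enumerate(zip(window, motif)) if a != b]
        if len(mismatches) == 1:
            j = mismatches[0]
            out.append((i + 1, j + 1, window[j], motif[j]))
    return out


def cysteine_profile(
    protein: str,
    annotation: ProteinAnnotation | None = None,
    reference_protein: str | None = None,
) -> CysteineProfile:
    """Cysteine count, positions, per-domain distribution.

    When a reference protein is given, cysteine positions present in only
    one of the two sequences are paired off in order as positional moves
    (raw protein coordinates, not alignment columns).
    """
    seq = protein.upper()
    positions = [i + 1 for i, aa in enumerate(seq) if aa == "C"]
    per_domain: dict[str, int] = {}
    if annotation is not None:
        for label, _, _ in annotation.domains:
            per_domain.setdefault(label, 0)
        for pos in positions:
            per_domain[annotation.domain_of(pos)] += 1
    moved: list[tuple[int, int]] = []
    if reference_protein is not None:
        ref_pos = [i + 1 for i, aa in enumerate(reference_protein.upper()) if aa == "C"]
        only_ref = [p for p in ref_pos if p not in positions]
        only_obs = [p for p in positions if p not in ref_pos]
        moved = list(zip(only_ref, only_obs))
    return CysteineProfile(
        total=len(positions),
        positions=positions,
        per_domain=per_domain,
        moved_positions=moved,
    )


def count_repeat_units(
    protein: str, motif: str | list[str], allow_overlap: bool = False
) -> int:
    """Occurrences of a repeat unit (or unit family) in a protein.

    Default is a non-overlapping greedy left-to-right count, the natural
    way tandem units are tallied; ``allow_overlap`` counts every window.
    A list of literals (e.g. the four PFPQ(1-2)(PQQ)(1-2) expansions) is
    matched longest-first at each position.
    """
    motifs = [motif] if isinstance(motif, str) else list(motif)
    if not motifs or any(not m for m in motifs):
        raise ValueError("empty motif")
    motifs.sort(key=len, reverse=True)
    seq = protein.upper()
    count = 0
    if allow_overlap:
        for m in motifs:
            start = seq.find(m)
            while start != -1:
                count += 1
                start = seq.find(m, start + 1)
        return count
    i = 0
    while i < len(seq):
        for m in motifs:
            if seq.startswith(m, i):
                count += 1
                i += len(m)
                break
        else:
            i += 1
    return count


def qpf_ratio(region: str) -> tuple[tuple[float, float, float], tuple[int, int, int]]:
    """Q/P/F fractions among Q+P+F residues and the nearest small-integer ratio.

    The integer ratio comes from rounding 8x the fractions and reducing by
    their gcd, so a canonical ARQ/E-type region reads 4:3:1.
    """
    seq = region.upper()
    if not seq:
        raise ValueError("empty region")
    q, p, f = seq.count("Q"), seq.count("P"), seq.count("F")
    total = q + p + f
    if total == 0:
        raise ValueError("region contains no Q, P or F residues")
    fracs = (q / total, p / total, f / total)
    ints = [round(8 * x) for x in fracs]
    g = math.gcd(math.gcd(ints[0], ints[1]), ints[2]) or 1
    ratio = tuple(x // g for x in ints)
    return fracs, ratio  # type: ignore[return-value]


def classify_omega(mature_protein: str, tolerance: float = 0.05) -> str:
    """ω-gliadin type from the first three mature residues.

    ARQ/ARE → ARQ/E; KEL, SRL and TRQ are their own types.  Any other
    start whose overall Q:P:F composition sits within ``tolerance`` of the
    canonical 4:3:1 fractions is an ARQ/E-like variant (the published ARH
    start behaves this way); otherwise unknown.
    """
    seq = mature_protein.upper()
    if len(seq) < 3:
        raise ValueError("mature protein shorter than 3 residues")
    head = seq[:3]
    if head in ("ARQ", "ARE"):
        return "ARQ/E"
    if head in ("KEL", "SRL", "TRQ"):
        return head
    fracs, _ = qpf_ratio(seq)
    if all(abs(a - b) <= tolerance for a, b in zip(fracs, ARQE_QPF_FRACTIONS)):
        return "ARQ/E-like variant"
    return "unknown"


def polyq_variants(annotation: ProteinAnnotation) -> tuple[list[str], list[str]]:
    """Non-glutamine residues inside the α QI and QII tracts."""
    qi = annotation.domain_sequence("QI")
    qii = annotation.domain_sequence("QII")
    return (
        [aa for aa in qi if aa != "Q"],
        [aa for aa in qii if aa != "Q"],
    )


_ALPHA_EPITOPE_NAMES = {
    "DQ2.5-glia-α1a", "DQ2.5-glia-α1b", "DQ2.5-glia-α2", "DQ2.5-glia-α3",
    "DQ8-glia-α1", "19-residue-peptide", "12-residue-peptide",
}


def classify_alpha_group(
    annotation: ProteinAnnotation,
    epitope_hits: list[EpitopeHit],
    qi_variants: list[str] | None = None,
    qii_variants: list[str] | None = None,
) -> str:
    """α-gliadin group from polyQ point mutations and epitope content.

    Group I: a Q→A substitution in QI together with the DQ8-glia-α1
    epitope.  Group II: a Q→K substitution in QII together with both
    DQ2.5-glia-α1a and DQ2.5-glia-α3.  Group III: pure-Q tracts and 3–4
    distinct α epitopes.  Everything else is unclassified.
    """
    if annotation is None:
        raise ValueError("annotation required for α group classification")
    if qi_variants is None or qii_variants is None:
        qi_variants, qii_variants = polyq_variants(annotation)
    names = {n for h in epitope_hits for n in h.epitope_names}
    alpha_names = names & _ALPHA_EPITOPE_NAMES
    if "A" in qi_variants and "DQ8-glia-α1" in names:
        return "I"
    if "K" in qii_variants and {"DQ2.5-glia-α1a", "DQ2.5-glia-α3"} <= names:
        return "II"
    if not qi_variants and not qii_variants and len(alpha_names) in (3, 4):
        return "III"
    return "unclassified"


def epitope_table(
    gene_ids: list[str],
    hits_per_gene: dict[str, list[EpitopeHit]],
    library: list[EpitopeDef] | None = None,
) -> pd.DataFrame:
    """Gene x epitope count matrix mirroring a toxic-epitope content table."""
    library = library if library is not None else load_epitope_library()
    names = sorted({e.name for e in library})
    rows = []
    for gid in gene_ids:
        counts = dict.fromkeys(names, 0)
        for hit in hits_per_gene.get(gid, []):
            for n in hit.epitope_names:
                counts[n] += 1
        counts["gene"] = gid
        rows.append(counts)
    return pd.DataFrame(rows).set_index("gene")[names]
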