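"""ORF status of gliadin coding sequences.

Translates CDS fragments, locates internal stop codons, detects
frameshifting indels against a full-ORF homolog, and classifies the
mutational origin of each stop.  In prolamin families the dominant
pseudogenization route is a C-to-T transition at the first position of a
glutamine codon (CAA→TAA, CAG→TAG) or, rarely, of a CGA arginine codon
(CGA→TGA); anything that a single such transition cannot explain is left
``unexplained``.

Input convention: the CDS excludes the terminal stop codon, so a full-ORF
fragment of 3N bp encodes exactly N residues.  Sequences that do end in a
stop are trimmed with a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import edlib
from Bio.Align import PairwiseAligner
from Bio.Seq import Seq

STOP_CODONS = {"TAA", "TAG", "TGA"}

#: stop origins explainable by a single C->T at codon position 1
ORIGIN_CAA = "CAA->TAA"
ORIGIN_CAG = "CAG->TAG"
ORIGIN_CGA = "CGA->TGA"
ORIGIN_FRAMESHIFT = "frameshift-induced"
ORIGIN_UNEXPLAINED = "unexplained"

_C_TO_T = {"CAA": "TAA", "CAG": "TAG", "CGA": "TGA"}

FULL_ORF = "full_orf"
PSEUDO_STOP = "pseudo_stop"
PSEUDO_FRAMESHIFT = "pseudo_frameshift"


@dataclass
class StopCodonEvent:
    codon_index: int                      # 1-based codon position in the CDS
    observed_codon: str
    reference_codon: str | None = None
    origin: str = ORIGIN_UNEXPLAINED

    def __post_init__(self) -> None:
        if self.observed_codon not in STOP_CODONS:
            raise ValueError(f"{self.observed_codon} is not a stop codon")


@dataclass
class FrameshiftEvent:
    cds_position: int                     # 1-based bp, first affected reference base
    kind: str                             # "insertion" | "deletion"
    length: int

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("indel length must be >= 1")
        if self.kind not in ("insertion", "deletion"):
            raise ValueError(f"unknown indel kind {self.kind!r}")


@dataclass
class OrfResult:
    gene_id: str
    status: str
    protein: str                          # conceptual translation, stops as '*'
    stop_events: list[StopCodonEvent] = field(default_factory=list)
    frameshift_events: list[FrameshiftEvent] = field(default_factory=list)
    reference_id: str | None = None


def trim_terminal_stop(nt: str) -> str:
    """Drop a trailing stop codon, warning — catalogue lengths exclude it."""
    nt = nt.upper()
    if len(nt) % 3 == 0 and nt[-3:] in STOP_CODONS:
        warnings.warn("CDS ends in a stop codon; trimming it", stacklevel=2)
        return nt[:-3]
    return nt


def translate_cds(nt: str) -> str:
    """Translate an in-frame CDS with the standard code; stops become ``*``.

    Raises if the length is not divisible by 3 (frameshift handling is the
    caller's job) or on non-ACGTN characters.  A missing ATG start only
    warns.
    """
    nt = nt.upper()
    if not nt:
        raise ValueError("empty CDS")
    if len(nt) % 3 != 0:
        raise ValueError(f"CDS length {len(nt)} not divisible by 3")
    bad = set(nt) - set("ACGTN")
    if bad:
        raise ValueError(f"illegal nucleotide characters: {sorted(bad)}")
    if not nt.startswith("ATG"):
        warnings.warn("CDS does not start with ATG", stacklevel=2)
    return str(Seq(nt).translate())


def find_internal_stops(nt: str) -> list[StopCodonEvent]:
    """All stop codons in the given reading frame, sorted by codon index.

    Origins are left ``unexplained``; run :func:`classify_stop_origin`
    against an aligned full-ORF homolog to resolve them.
    """
    nt = nt.upper()
    if len(nt) % 3 != 0:
        raise ValueError(f"CDS length {len(nt)} not divisible by 3")
    events = []
    for i in range(0, len(nt), 3):
        codon = nt[i : i + 3]
        if codon in STOP_CODONS:
            events.append(StopCodonEvent(codon_index=i // 3 + 1, observed_codon=codon))
    return events


def classify_stop_origin(
    event: StopCodonEvent, reference_codon: str | None
) -> StopCodonEvent:
    """Resolve a stop's mutational origin from the aligned reference codon.

    CAA→TAA, CAG→TAG and CGA→TGA are each a single C→T at codon position 1;
    a gapped reference codon marks the stop as frameshift-induced; anything
    else is unexplained.
    """
    if reference_codon is None or "-" in reference_codon:
        origin = ORIGIN_FRAMESHIFT
    elif _C_TO_T.get(reference_codon.upper()) == event.observed_codon:
        origin = f"{reference_codon.upper()}->{event.observed_codon}"
    else:
        origin = ORIGIN_UNEXPLAINED
    return replace(event, reference_codon=reference_codon, origin=origin)


# ---------------------------------------------------------------------------
# alignment helpers

def _aligner(match: float = 1, mismatch: float = -1,
             gap_open: float = -5, gap_extend: float = -1) -> PairwiseAligner:
    a = PairwiseAligner()
    a.mode = "global"
    a.match_score = match
    a.mismatch_score = mismatch
    a.open_gap_score = gap_open
    a.extend_gap_score = gap_extend
    return a


def _left_normalize(seq: str, pos: int, length: int) -> int:
    """Shift an indel of ``seq[pos:pos+length]`` to its leftmost equivalent
    placement (0-based), the usual convention inside repeat runs."""
    while pos > 0 and seq[pos - 1] == seq[pos + length - 1]:
        pos -= 1
    return pos


def _alignment_maps(reference: str, observed: str, aligner: PairwiseAligner):
    """Global alignment; returns (obs->ref position map, indel list).

    The map has one entry per observed base: the 0-based reference index it
    aligns to, or -1 for inserted bases.  Indels are left-normalized
    ``(ref_pos0, kind, length)`` tuples.
    """
    aln = aligner.align(reference, observed)[0]
    ref_blocks, obs_blocks = aln.aligned
    obs_to_ref = [-1] * len(observed)
    indels: list[tuple[int, str, int]] = []
    prev_r_end = prev_o_end = 0
    for (rs, re_), (os_, oe) in zip(ref_blocks, obs_blocks):
        if rs > prev_r_end:  # deletion: reference bases missing from observed
            length = rs - prev_r_end
            pos = _left_normalize(reference, prev_r_end, length)
            indels.append((pos, "deletion", length))
        if os_ > prev_o_end:  # insertion: observed bases absent from reference
            # reported at the reference base before which the insertion sits
            indels.append((rs, "insertion", os_ - prev_o_end))
        for k in range(re_ - rs):
            obs_to_ref[os_ + k] = rs + k
        prev_r_end, prev_o_end = re_, oe
    if len(reference) > prev_r_end:
        length = len(reference) - prev_r_end
        pos = _left_normalize(reference, prev_r_end, length)
        indels.append((pos, "deletion", length))
    if len(observed) > prev_o_end:
        indels.append((len(reference), "insertion", len(observed) - prev_o_end))
    return obs_to_ref, indels


def detect_frameshift(
    nt: str, reference_nt: str, aligner: PairwiseAligner | None = None
) -> list[FrameshiftEvent]:
    """Frame-breaking indels of ``nt`` relative to a full-ORF homolog.

    Only indels whose length is not a multiple of 3 are reported; positions
    are 1-based reference bp, left-normalized within repeat runs.
    """
    nt, reference_nt = nt.upper(), reference_nt.upper()
    aligner = aligner or _aligner()
    _, indels = _alignment_maps(reference_nt, nt, aligner)
    return [
        FrameshiftEvent(cds_position=pos + 1, kind=kind, length=length)
        for pos, kind, length in indels
        if length % 3 != 0
    ]


def nucleotide_identity(a: str, b: str) -> float:
    """Global (NW) identity, 1 - edit distance / longer length."""
    d = edlib.align(a.upper(), b.upper(), mode="NW", task="distance")["editDistance"]
    return 1.0 - d / max(len(a), len(b))


def pick_reference(nt: str, panel: dict[str, str]) -> str | None:
    """Best full-ORF reference: highest identity, then longest, then id."""
    if not panel:
        return None
    scored = [
        (-nucleotide_identity(nt, ref), -len(ref), ref_id)
        for ref_id, ref in panel.items()
    ]
    return min(scored)[2]


def classify_orf(
    nt: str,
    reference_panel: dict[str, str] | None = None,
    gene_id: str = "",
    aligner: PairwiseAligner | None = None,
) -> OrfResult:
    """Full ORF / pseudo-stop / pseudo-frameshift call for one CDS.

    The reference (best nucleotide identity in the panel) serves two jobs:
    mapping each internal stop to its ancestral codon for origin calling,
    and exposing frame-breaking indels.  Per the classification rule, a
    frame-breaking indel makes the gene ``pseudo_frameshift``; otherwise
    any internal stop makes it ``pseudo_stop``.
    """
    if not nt:
        raise ValueError("empty input sequence")
    nt = trim_terminal_stop(nt)
    panel = reference_panel or {}
    aligner = aligner or _aligner()

    in_frame = len(nt) % 3 == 0
    stops = find_internal_stops(nt) if in_frame else []
    if in_frame and not stops:
        return OrfResult(gene_id=gene_id, status=FULL_ORF, protein=translate_cds(nt))

    ref_id = pick_reference(nt, panel)
    frameshifts: list[FrameshiftEvent] = []
    if ref_id is not None:
        ref = panel[ref_id].upper()
        obs_to_ref, indels = _alignment_maps(ref, nt, aligner)
        frameshifts = [
            FrameshiftEvent(cds_position=p + 1, kind=k, length=ln)
            for p, k, ln in indels
            if ln % 3 != 0
        ]
        resolved = []
        for ev in stops:
            lo = (ev.codon_index - 1) * 3
            refpos = [obs_to_ref[lo + k] for k in range(3)]
            if -1 in refpos or refpos != list(range(refpos[0], refpos[0] + 3)):
                ref_codon = "---"
            else:
                ref_codon = ref[refpos[0] : refpos[0] + 3]
            resolved.append(classify_stop_origin(ev, ref_codon))
        stops = resolved
    elif not in_frame:
        # no reference: frame break of unknown position
        frameshifts = [FrameshiftEvent(cds_position=1, kind="deletion",
                                       length=(3 - len(nt) % 3) % 3 or 1)]

    if not in_frame:
        protein = translate_cds(nt[: len(nt) - len(nt) % 3])
    else:
        protein = translate_cds(nt)

    status = PSEUDO_FRAMESHIFT if frameshifts else PSEUDO_STOP
    return OrfResult(
        gene_id=gene_id,
        status=status,
        protein=protein,
        stop_events=stops,
        frameshift_events=frameshifts,
        reference_id=ref_id,
    )


def orf_report(results: list[OrfResult]):
    """Per-gene TSV-ready table of ORF calls and their events."""
    import pandas as pd

    return pd.DataFrame(
        {
            "gene": [r.gene_id for r in results],
            "status": [r.status for r in results],
            "n_internal_stops": [len(r.stop_events) for r in results],
            "stop_positions": [
                ";".join(str(e.codon_index) for e in r.stop_events) for r in results
            ],
            "stop_origins": [
                ";".join(e.origin for e in r.stop_events) for r in results
            ],
            "frameshift_positions": [
                ";".join(f"{e.cds_position}{e.kind[0]}{e.length}" for e in r.frameshift_events)
                for r in results
            ],
            "reference": [r.reference_id or "" for r in results],
        }
    )
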