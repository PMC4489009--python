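"""Gliadin type inference and domain segmentation.

Each gliadin class has a fixed domain order:

* α — signal, repetitive, QI, UI, QII, UII (two polyglutamine stretches
  separating two unique C-terminal domains),
* γ — signal, I, II, III, IV, V (repetitive domain II of
  PFPQ(1-2)(PQQ)(1-2) units, polyglutamine region IV),
* ω — signal, N-terminal, repetitive, C-terminal (hepta/octapeptide
  repeats, no cysteines).

Segmentation always yields exactly that label order as a partition of the
protein; individual segments may be empty.  The signal peptide is a fixed
per-type length (a config default, not a predicted cleavage site): 20
residues for α and γ, 19 for ω.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

ALPHA, GAMMA, OMEGA, UNKNOWN = "alpha", "gamma", "omega", "unknown"

DOMAIN_ORDER = {
    ALPHA: ["signal", "repetitive", "QI", "UI", "QII", "UII"],
    GAMMA: ["signal", "I", "II", "III", "IV", "V"],
    OMEGA: ["signal", "N-terminal", "repetitive", "C-terminal"],
}

DEFAULT_SIGNAL_LENGTH = {ALPHA: 20, GAMMA: 20, OMEGA: 19}

#: expansions of the γ repeat unit PFPQ(1-2)(PQQ)(1-2)
GAMMA_REPEAT_UNITS = ["PFPQPQQPQQ", "PFPQQPQQPQQ", "PFPQPQQ", "PFPQQPQQ"]

#: ω repetitive vocabulary: heptapeptide, octapeptide and the QQQP filler
OMEGA_REPEAT_UNITS = ["PFPQQPQQ", "PFPQPQQ", "QQQP"]


@dataclass
class ProteinAnnotation:
    """A protein partitioned into ordered, contiguous domain segments.

    ``domains`` holds ``(label, start, end)`` with 1-based inclusive
    coordinates; an empty segment is encoded as ``end == start - 1``.
    """

    gene_id: str
    protein: str
    gliadin_type: str
    domains: list[tuple[str, int, int]]
    mature_start: int                      # first residue after the signal
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        pos = 1
        for label, start, end in self.domains:
            if start != pos:
                raise ValueError(
                    f"{self.gene_id}: domain {label} starts at {start}, expected {pos}"
                )
            if end < start - 1:
                raise ValueError(f"{self.gene_id}: domain {label} has end < start-1")
            pos = end + 1
        if pos != len(self.protein) + 1:
            raise ValueError(
                f"{self.gene_id}: domains cover 1..{pos - 1}, protein has "
                f"{len(self.protein)} residues"
            )

    def domain_of(self, position: int) -> str:
        """Label of the segment containing a 1-based residue position."""
        for label, start, end in self.domains:
            if start <= position <= end:
                return label
        raise ValueError(f"position {position} outside 1..{len(self.protein)}")

    def domain_span(self, label: str) -> tuple[int, int]:
        for lab, start, end in self.domains:
            if lab == label:
                return start, end
        raise KeyError(label)

    def domain_sequence(self, label: str) -> str:
        start, end = self.domain_span(label)
        return self.protein[start - 1 : end]

    @property
    def mature_protein(self) -> str:
        return self.protein[self.mature_start - 1 :]


# ---------------------------------------------------------------------------
# polyglutamine tracts


def find_polyq_tracts(
    seq: str,
    min_len: int = 6,
    q_fraction: float = 0.8,
    merge_gap: int = 2,
) -> list[tuple[int, int]]:
    """Maximal polyQ tracts as 0-based half-open ``(start, end)`` intervals.

    A tract starts and ends with Q, is at least ``min_len`` long and at
    least ``q_fraction`` glutamine.  Q runs separated by at most
    ``merge_gap`` non-Q residues are merged when the merged stretch still
    satisfies the Q fraction, so a single substituted residue inside a
    tract does not split it.
    """
    runs = [(m.start(), m.end()) for m in re.finditer(r"Q+", seq)]
    merged: list[list[int]] = []
    for start, end in runs:
        if merged and start - merged[-1][1] <= merge_gap:
            cand_start, cand_end = merged[-1][0], end
            q = seq[cand_start:cand_end].count("Q")
            if q / (cand_end - cand_start) >= q_fraction:
                merged[-1][1] = end
                continue
        merged.append([start, end])
    return [(s, e) for s, e in merged if e - s >= min_len]


# ---------------------------------------------------------------------------
# repeat-covered regions (γ domain II, ω repetitive)


def _unit_matches(seq: str, units: list[str]) -> list[tuple[int, int]]:
    """All (overlapping) unit occurrences as 0-based half-open intervals."""
    hits = []
    for unit in units:
        start = seq.find(unit)
        while start != -1:
            hits.append((start, start + len(unit)))
            start = seq.find(unit, start + 1)
    return sorted(hits)


def repeat_region(
    seq: str, units: list[str], min_coverage: float = 0.6
) -> tuple[int, int] | None:
    """Largest region covered >= ``min_coverage`` by repeat-unit matches.

    Unit matches are merged into covered intervals; every span from one
    covered interval to a later one is scored, and the longest span whose
    covered fraction clears the threshold wins (leftmost on ties).
    Returns a 0-based half-open interval or None when no unit matches.
    """
    matches = _unit_matches(seq, units)
    if not matches:
        return None
    covered: list[list[int]] = []
    for s, e in matches:
        if covered and s <= covered[-1][1]:
            covered[-1][1] = max(covered[-1][1], e)
        else:
            covered.append([s, e])
    best: tuple[int, tuple[int, int]] | None = None
    for i in range(len(covered)):
        cov = 0
        for j in range(i, len(covered)):
            cov += covered[j][1] - covered[j][0]
            span = (covered[i][0], covered[j][1])
            length = span[1] - span[0]
            if cov / length >= min_coverage:
                key = (length, -span[0])
                if best is None or key > best[0]:
                    best = (key, span)
    return best[1] if best else None


# ---------------------------------------------------------------------------
# type inference


def infer_gliadin_type(protein: str, min_length: int = 50) -> str:
    """Score-based α/γ/ω call from cysteine count and repeat content.

    Mature α gliadins carry 5–7 cysteines and two separated polyQ tracts;
    γ carry 8 cysteines and PFPQ(1-2)(PQQ)(1-2) repeats; ω carry none and
    are built from hepta/octapeptide units.  Returns ``unknown`` when no
    score reaches the decision threshold or on a tie.
    """
    seq = protein.strip().upper()
    if len(seq) < min_length:
        raise ValueError(f"protein too short to type ({len(seq)} residues)")
    bad = set(seq) - set("ACDEFGHIKLMNPQRSTVWYX*")
    if bad:
        raise ValueError(f"non-standard residues: {sorted(bad)}")

    n_cys = seq.count("C")
    tracts = find_polyq_tracts(seq)
    n_gamma_units = len(_unit_matches(seq, GAMMA_REPEAT_UNITS))
    n_omega_units = len(_unit_matches(seq, OMEGA_REPEAT_UNITS))

    scores = {
        ALPHA: 2 * (5 <= n_cys <= 7) + 2 * (len(tracts) >= 2),
        GAMMA: 2 * (n_cys == 8) + 2 * (n_gamma_units >= 3) + (len(tracts) == 1),
        OMEGA: (n_cys == 0) * (2 + 2 * (n_omega_units >= 3)),
    }
    best = max(scores.values())
    winners = [t for t, s in scores.items() if s == best]
    if best < 3 or len(winners) > 1:
        return UNKNOWN
    return winners[0]


# ---------------------------------------------------------------------------
# segmentation


def segment_domains(
    protein: str,
    gliadin_type: str,
    gene_id: str = "",
    signal_length: int | None = None,
    min_polyq: int = 6,
    polyq_q_fraction: float = 0.8,
    polyq_merge_gap: int = 2,
    repeat_coverage: float = 0.6,
) -> ProteinAnnotation:
    """Partition a typed gliadin protein into its ordered domains.

    The signal is the first ``signal_length`` residues (per-type default).
    α: the first polyQ tract of the mature protein is QI, the second QII,
    with repetitive/UI/UII filling the gaps.  γ: domain II is the largest
    repeat-covered region, domain IV the longest polyQ tract after it.
    ω: the repetitive region is the largest region covered by
    hepta/octapeptide units.  An α protein with fewer than two tracts gets
    an empty QII and a warning flag rather than an error.
    """
    if gliadin_type not in DOMAIN_ORDER:
        raise ValueError(f"unknown gliadin type {gliadin_type!r}")
    seq = protein.upper()
    n = len(seq)
    sig = signal_length if signal_length is not None else DEFAULT_SIGNAL_LENGTH[gliadin_type]
    sig = min(sig, n)
    mature = seq[sig:]
    warnings_: list[str] = []

    def tract_spans() -> list[tuple[int, int]]:
        return [
            (s + sig, e + sig)
            for s, e in find_polyq_tracts(
                mature, min_polyq, polyq_q_fraction, polyq_merge_gap
            )
        ]

    # all coordinates below are 0-based half-open in the full protein,
    # converted to 1-based inclusive at the end
    cuts: list[tuple[str, int, int]] = [("signal", 0, sig)]

    if gliadin_type == ALPHA:
        tracts = tract_spans()
        if len(tracts) < 2:
            warnings_.append("fewer than two polyQ tracts; QII left empty")
        qi = tracts[0] if tracts else (n, n)
        qii = tracts[1] if len(tracts) > 1 else (n, n)
        cuts += [
            ("repetitive", sig, qi[0]),
            ("QI", qi[0], qi[1]),
            ("UI", qi[1], qii[0]),
            ("QII", qii[0], qii[1]),
            ("UII", qii[1], n),
        ]
    elif gliadin_type == GAMMA:
        span = repeat_region(mature, GAMMA_REPEAT_UNITS, repeat_coverage)
        if span is None:
            warnings_.append("no repeat units found; domain II left empty")
            ii = (sig, sig)
        else:
            ii = (span[0] + sig, span[1] + sig)
        after = seq[ii[1] :]
        tr = find_polyq_tracts(after, min_polyq, polyq_q_fraction, polyq_merge_gap)
        if tr:
            iv = max(tr, key=lambda t: (t[1] - t[0], -t[0]))
            iv = (iv[0] + ii[1], iv[1] + ii[1])
        else:
            warnings_.append("no polyQ tract after domain II; domain IV left empty")
            iv = (n, n)
        cuts += [
            ("I", sig, ii[0]),
            ("II", ii[0], ii[1]),
            ("III", ii[1], iv[0]),
            ("IV", iv[0], iv[1]),
            ("V", iv[1], n),
        ]
    else:  # omega
        span = repeat_region(mature, OMEGA_REPEAT_UNITS, repeat_coverage)
        if span is None:
            warnings_.append("no repeat units found; repetitive region left empty")
            rep = (n, n)
        else:
            rep = (span[0] + sig, span[1] + sig)
        cuts += [
            ("N-terminal", sig, rep[0]),
            ("repetitive", rep[0], rep[1]),
            ("C-terminal", rep[1], n),
        ]

    domains = [(label, s + 1, e) for label, s, e in cuts]
    return ProteinAnnotation(
        gene_id=gene_id,
        protein=seq,
        gliadin_type=gliadin_type,
        domains=domains,
        mature_start=sig + 1,
        warnings=warnings_,
    )


def polyq_length_profile(annotations: list[ProteinAnnotation]):
    """Per-gene QI/QII residue lengths and their nucleotide extents.

    The nucleotide extent of a tract is 3 bp per residue; the published α
    families vary QI from 9 residues (27 bp) to 33 residues (99 bp).
    """
    import pandas as pd

    rows = []
    for ann in annotations:
        if ann.gliadin_type != ALPHA:
            raise ValueError(f"{ann.gene_id}: polyQ profile is defined for α only")
        qi_s, qi_e = ann.domain_span("QI")
        qii_s, qii_e = ann.domain_span("QII")
        qi_len = max(0, qi_e - qi_s + 1)
        qii_len = max(0, qii_e - qii_s + 1)
        rows.append(
            {
                "gene": ann.gene_id,
                "qi_residues": qi_len,
                "qi_nt": 3 * qi_len,
                "qii_residues": qii_len,
                "qii_nt": 3 * qii_len,
            }
        )
    df = pd.DataFrame(rows)
    df.attrs["qi_nt_range"] = (
        (int(df["qi_nt"].min()), int(df["qi_nt"].max())) if len(df) else (0, 0)
    )
    return df
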