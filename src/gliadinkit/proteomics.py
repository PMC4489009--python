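"""In-silico chymotryptic digestion and 2-DE spot assignment.

Peptide evidence links gel spots to the predicted proteins of active
genes: a spot is uniquely assigned when one gene contributes a peptide
found in no other protein; spots whose peptides are all shared stay with
the intersection-supported gene group, and their volume is never split
among members.  Matching is sequence-level substring matching — spectral
scoring is out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from pyteomics import mass as _pyteomics_mass

from .seqio import SpotTableRow

#: chymotrypsin high-specificity residues plus L/M, no cleavage before P
CHYMO_RESIDUES = "FYWLM"
CHYMO_RESIDUES_STRICT = "FYW"


@dataclass
class Peptide:
    sequence: str
    parent_id: str
    start: int                      # 1-based position in the parent protein
    missed_cleavages: int
    monoisotopic_mass: float

    def __post_init__(self) -> None:
        if self.monoisotopic_mass <= 0:
            raise ValueError("non-positive peptide mass")


@dataclass
class SpotAssignment:
    spot_id: int
    matched_genes: list[str]
    unique: bool
    supporting_peptides: dict[str, list[str]] = field(default_factory=dict)
    unique_peptides: dict[str, list[str]] = field(default_factory=dict)


def cleavage_sites(protein: str, residues: str = CHYMO_RESIDUES) -> list[int]:
    """Internal cut points (0-based index of the first residue after the
    cut); cleavage is C-terminal to F/Y/W/L/M except before a proline."""
    seq = protein.upper()
    return [
        i + 1
        for i in range(len(seq) - 1)
        if seq[i] in residues and seq[i + 1] != "P"
    ]


def chymotryptic_digest(
    protein: str,
    parent_id: str = "",
    max_missed: int = 2,
    min_len: int = 5,
    residues: str = CHYMO_RESIDUES,
) -> list[Peptide]:
    """All chymotryptic peptides with 0..``max_missed`` missed cleavages.

    With ``min_len=1`` and ``max_missed=0`` the peptides tile the protein
    exactly.
    """
    seq = protein.upper()
    bounds = [0] + cleavage_sites(seq, residues) + [len(seq)]
    peptides = []
    for i in range(len(bounds) - 1):
        for j in range(i + 1, min(i + 2 + max_missed, len(bounds))):
            pep = seq[bounds[i] : bounds[j]]
            if len(pep) < min_len:
                continue
            peptides.append(
                Peptide(
                    sequence=pep,
                    parent_id=parent_id,
                    start=bounds[i] + 1,
                    missed_cleavages=j - i - 1,
                    monoisotopic_mass=_pyteomics_mass.fast_mass(pep),
                )
            )
    return peptides


def match_peptides(
    observed_peptides: list[str], proteome: dict[str, str]
) -> dict[str, set[str]]:
    """Exact substring match of each peptide against every predicted protein."""
    if not proteome:
        raise ValueError("empty proteome")
    return {
        pep: {gene for gene, prot in proteome.items() if pep.upper() in prot.upper()}
        for pep in observed_peptides
    }


def assign_spot(
    spot_id: int, peptides: list[str], proteome: dict[str, str]
) -> SpotAssignment:
    """Assign one spot from its identified peptides.

    Unique when exactly one gene owns a peptide found in no other protein;
    several genes with exclusive peptides mean a mixture; no exclusive
    peptide at all leaves the intersection-supported group (falling back
    to the union when the intersection is empty).  No peptide matching
    anything yields an unassigned spot.
    """
    if not peptides:
        raise ValueError(f"spot {spot_id}: no peptides supplied")
    matches = match_peptides(peptides, proteome)
    matched = {p: gs for p, gs in matches.items() if gs}
    if not matched:
        return SpotAssignment(spot_id=spot_id, matched_genes=[], unique=False)
    support: dict[str, list[str]] = {}
    for pep, genes in matched.items():
        for g in genes:
            support.setdefault(g, []).append(pep)
    exclusive = {
        g: [p for p in peps if matched[p] == {g}] for g, peps in support.items()
    }
    exclusive = {g: ps for g, ps in exclusive.items() if ps}
    if len(exclusive) == 1:
        gene = next(iter(exclusive))
        return SpotAssignment(
            spot_id=spot_id,
            matched_genes=[gene],
            unique=True,
            supporting_peptides=support,
            unique_peptides=exclusive,
        )
    if len(exclusive) > 1:  # a mixture of distinguishable proteins
        genes = sorted(exclusive)
    else:
        inter = set.intersection(*matched.values())
        genes = sorted(inter) if inter else sorted(support)
    return SpotAssignment(
        spot_id=spot_id,
        matched_genes=genes,
        unique=False,
        supporting_peptides=support,
        unique_peptides=exclusive,
    )


def _gene_class(gene: str) -> str:
    low = gene.lower()
    for token, cls in (
        ("α", "α"), ("alpha", "α"), ("-a-", "α"),
        ("γ", "γ"), ("gamma", "γ"), ("-g-", "γ"),
        ("ω", "ω"), ("omega", "ω"), ("-w-", "ω"),
    ):
        if token in low:
            return cls
    return "unknown"


def aggregate_volumes(
    spots: list[SpotTableRow],
    assignments: dict[int, SpotAssignment] | None = None,
) -> dict[str, dict]:
    """Percent-volume totals per gene, per ambiguity group and per class.

    Spots assigned to several genes contribute their whole volume to the
    group (joined gene names), never fractionally to members.  Raises no
    error on a total above 100.5 but flags it.
    """
    by_spot: dict[int, dict] = {}
    for row in spots:
        entry = by_spot.setdefault(
            row.spot_id, {"volume": row.percent_volume, "genes": []}
        )
        if abs(entry["volume"] - row.percent_volume) > 1e-9:
            raise ValueError(f"spot {row.spot_id}: inconsistent %Vol across rows")
        if row.assigned_gene:
            entry["genes"].append(row.assigned_gene)

    per_gene: dict[str, float] = {}
    per_group: dict[str, float] = {}
    per_class: dict[str, float] = {}
    unassigned = 0.0
    for spot_id, entry in by_spot.items():
        genes = entry["genes"]
        if assignments is not None and spot_id in assignments:
            genes = assignments[spot_id].matched_genes
        vol = entry["volume"]
        if not genes:
            unassigned += vol
            continue
        if len(genes) == 1:
            per_gene[genes[0]] = round(per_gene.get(genes[0], 0.0) + vol, 10)
        else:
            key = "+".join(sorted(genes))
            per_group[key] = round(per_group.get(key, 0.0) + vol, 10)
        cls = {_gene_class(g) for g in genes}
        label = cls.pop() if len(cls) == 1 else "mixed"
        per_class[label] = round(per_class.get(label, 0.0) + vol, 10)

    total = round(sum(e["volume"] for e in by_spot.values()), 10)
    return {
        "per_gene": per_gene,
        "per_group": per_group,
        "per_class": per_class,
        "unassigned": unassigned,
        "total": total,
        "total_exceeds_tolerance": total > 100.5,
    }


def spot_consistency(
    observed_mw_kd: float,
    observed_pi: float,
    candidates: dict[str, tuple[float, float]],
    tol_mw_kd: float = 3.0,
    tol_pi: float = 0.5,
) -> tuple[bool, dict[str, tuple[float, float]]]:
    """Check a spot's observed MW/pI against its candidates' predictions.

    Consistent when at least one candidate sits within both tolerances;
    deltas (observed - predicted) are returned for every candidate.
    """
    if not candidates:
        raise ValueError("no candidate predictions supplied")
    deltas = {
        gene: (observed_mw_kd - mw, observed_pi - pi)
        for gene, (mw, pi) in candidates.items()
    }
    ok = any(
        abs(dmw) <= tol_mw_kd and abs(dpi) <= tol_pi for dmw, dpi in deltas.values()
    )
    return ok, deltas


def assignment_table(assignments: dict[int, SpotAssignment]) -> pd.DataFrame:
    rows = []
    for spot_id in sorted(assignments):
        a = assignments[spot_id]
        rows.append(
            {
                "spot": spot_id,
                "genes": ";".join(a.matched_genes) or "unassigned",
                "unique": a.unique,
                "n_supporting_peptides": sum(
                    len(v) for v in a.supporting_peptides.values()
                ),
                "unique_peptides": ";".join(
                    p for ps in a.unique_peptides.values() for p in ps
                ),
            }
        )
    return pd.DataFrame(rows)
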