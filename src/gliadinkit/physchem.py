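"""Theoretical molecular weight and isoelectric point of predicted proteins.

MW is the sum of average residue masses plus one water — the gel-scale
quantity 2-DE spot tables print — and pI is the pH at which the
Henderson–Hasselbalch net charge vanishes, found by bisection.  The pKa
set is selectable (Bjellqvist by default, EMBOSS as an alternative) and is
recorded in every output row, since published pI values rarely state
theirs.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

#: average (isotope-weighted) residue masses, Da
AVERAGE_RESIDUE_MASS = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886, "C": 103.1388,
    "E": 129.1155, "Q": 128.1307, "G": 57.0519, "H": 137.1411, "I": 113.1594,
    "L": 113.1594, "K": 128.1741, "M": 131.1926, "F": 147.1766, "P": 97.1167,
    "S": 87.0782, "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}
WATER_MASS = 18.0153

#: side-chain and terminal pKa sets; positive groups then negative groups
PKA_SETS: dict[str, dict[str, float]] = {
    "bjellqvist": {
        "Nterm": 7.50, "K": 10.00, "R": 12.00, "H": 5.98,
        "Cterm": 3.55, "D": 4.05, "E": 4.45, "C": 9.00, "Y": 10.00,
    },
    "emboss": {
        "Nterm": 8.60, "K": 10.80, "R": 12.50, "H": 6.50,
        "Cterm": 3.60, "D": 3.90, "E": 4.10, "C": 8.50, "Y": 10.10,
    },
}
_POSITIVE = ("K", "R", "H")
_NEGATIVE = ("D", "E", "C", "Y")


@dataclass
class PhysChem:
    mw_kd: float
    pi: float
    pka_set: str = "bjellqvist"

    def __post_init__(self) -> None:
        if self.mw_kd <= 0:
            raise ValueError("MW must be positive")
        if not 0 < self.pi < 14:
            raise ValueError("pI out of (0, 14)")


def _check_protein(protein: str) -> str:
    seq = protein.upper()
    if not seq:
        raise ValueError("empty sequence")
    bad = set(seq) - set(AVERAGE_RESIDUE_MASS)
    if bad:
        raise ValueError(f"non-standard residues: {sorted(bad)}")
    return seq


def molecular_weight(protein: str) -> float:
    """Average-mass molecular weight in daltons (residues + one water)."""
    seq = _check_protein(protein)
    return sum(AVERAGE_RESIDUE_MASS[aa] for aa in seq) + WATER_MASS


def net_charge(protein: str, ph: float, pka_set: str = "bjellqvist") -> float:
    """Henderson–Hasselbalch net charge at a given pH.

    Positive groups: the N-terminus plus K, R, H side chains; negative:
    the C-terminus plus D, E, C, Y.  Strictly decreasing in pH, so the
    zero crossing is unique.
    """
    seq = _check_protein(protein)
    pka = PKA_SETS[pka_set]
    pos = 1.0 / (1.0 + 10 ** (ph - pka["Nterm"]))
    for aa in _POSITIVE:
        pos += seq.count(aa) / (1.0 + 10 ** (ph - pka[aa]))
    neg = 1.0 / (1.0 + 10 ** (pka["Cterm"] - ph))
    for aa in _NEGATIVE:
        neg += seq.count(aa) / (1.0 + 10 ** (pka[aa] - ph))
    return pos - neg


def isoelectric_point(
    protein: str, pka_set: str = "bjellqvist", tolerance: float = 0.005
) -> float:
    """pH of zero net charge, by bisection on [0, 14]."""
    if pka_set not in PKA_SETS:
        raise KeyError(f"unknown pKa set {pka_set!r}; choose from {sorted(PKA_SETS)}")
    lo, hi = 0.0, 14.0
    while hi - lo > tolerance:
        mid = (lo + hi) / 2.0
        if net_charge(protein, mid, pka_set) > 0:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


def physchem(
    protein: str, pka_set: str = "bjellqvist", mature_start: int | None = None
) -> PhysChem:
    """MW (kD) and pI for a protein; pass ``mature_start`` (1-based) to
    compute on the signal-removed chain instead of the full prediction."""
    seq = protein if mature_start is None else protein[mature_start - 1 :]
    return PhysChem(
        mw_kd=molecular_weight(seq) / 1000.0,
        pi=isoelectric_point(seq, pka_set),
        pka_set=pka_set,
    )


def physchem_table(
    proteins: dict[str, str],
    pka_set: str = "bjellqvist",
    mature_starts: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Per-gene MW/pI table (2 decimals, as spot tables print them)."""
    scope = "mature" if mature_starts else "full"
    rows = []
    for gene, seq in proteins.items():
        start = (mature_starts or {}).get(gene)
        pc = physchem(seq, pka_set, start)
        rows.append(
            {
                "gene": gene,
                "mw_kd": round(pc.mw_kd, 2),
                "pi": round(pc.pi, 2),
                "pka_set": pka_set,
                "sequence_scope": scope,
            }
        )
    return pd.DataFrame(rows)
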