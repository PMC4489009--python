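"""Synthetic gliadin families with full ground truth.

Genes are constructed at the codon level, domain by domain, so that
nucleotide events are physically plantable: pseudogenization is a real
C→T transition at the first base of a CAA/CAG glutamine codon (rarely a
CGA arginine codon) or a real single-base deletion, applied to a
near-copy of an active gene of the same type — pseudogenes in these
families are structurally similar to the full-ORF genes they derive from.

The generator's defaults emulate the published study design: 23 α + 3 γ +
2 ω genes, ~43% pseudogenized, QI tracts of 9–33 residues (27–99 bp),
expression silent at 5 DPA, peaking at 15 DPA and declining through
25 DPA with a silent flag-leaf control (3 replicates, ~21.8 M reads per
library), and 2-DE spots derived from the physicochemistry and
chymotryptic digests of the active proteins, with near-identical proteins
merged into one ambiguous spot.

All randomness flows from a single seed through one generator.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import edlib
import numpy as np
import pandas as pd

from . import physchem as _physchem
from .domain_grammar import ALPHA, GAMMA, OMEGA
from .orf_core import FULL_ORF, PSEUDO_FRAMESHIFT, PSEUDO_STOP, _left_normalize
from .proteomics import chymotryptic_digest
from .seqio import SequenceRecord, SpotTableRow, write_fasta, write_spot_table

# ---------------------------------------------------------------------------
# building blocks (protein level; no C or Q in any signal peptide)

SIGNAL_ALPHA = "MKTFLILALLAIVATTATTA"          # 20 aa
SIGNAL_GAMMA = "MKTLLILTILAMAITIGTAN"          # 20 aa
SIGNAL_OMEGA = "MKTFLIFALLAIAATSAIA"           # 19 aa

#: α repetitive vocabulary — Q/P-rich, never ending in Q, never starting QQ,
#: so tract detection cannot bleed across the repetitive/QI boundary
ALPHA_REPEAT_UNITS = ["PQPQPFPP", "QPYPQPQP", "PQQPFPQP", "QPQPYPQP"]
ALPHA_REPEAT_CLOSER = "PQPYPSP"                # >=3 non-Q before QI

#: α unique domains; UI holds 4 cysteines, UII 2 plus the 12-residue
#: immunoreactive peptide with the R that disrupts DQ8-glia-α1 at its
#: fifth position (Q restores the epitope, the group-I configuration)
ALPHA_UI = "ISLHILPQSLIPCMDVVLQQHNIAHGRSQVLQQSTYQLLQELCCQHLWQIPEQSQCQAIHNVVHAIILH"
ALPHA_UII = "VSFQQPLQQYPLGQGSFRPSQQNPQAQGSVQPQQLPQFEEIRNLALQTLPAMCNVYIPPYCTIAPFGIFGTN"
_UII_12MER_OFFSET = ALPHA_UII.find("LGQGSFRPSQQN")          # 0-based, == 11
_UII_DQ8_OFFSET = ALPHA_UII.find("QGSFRPSQQ")               # 0-based, == 13
_UII_DQ8_R_OFFSET = _UII_DQ8_OFFSET + 4                     # the disrupting R

GAMMA_I = "NMQVDPSGQVQW"
GAMMA_REPEAT_POOL = ["PFPQPQQ", "PFPQPQQPQQ", "PFPQQPQQ", "PFPQQPQQPQQ"]
GAMMA_III = "SQILQQQLIPCRDVVLQQHSIAYGSSQVLQQSTCHVMQQQCCQQLRQIPCQSRCH"  # 6 Cys
GAMMA_V = "VMSHEQQEGVQILRPLFQLVQGQGIIQPEQSRQLEAIRSLVLQTLPSMCNVYVPPDCSTINVPYANIDAGIGGQ"  # 2 Cys

OMEGA_NTERM_TAIL = "LNPSNKEL"
OMEGA_REPEAT_POOL = ["PFPQQPQQ", "PFPQPQQ", "QQQP"]
OMEGA_REPEAT_WEIGHTS = [0.70, 0.15, 0.15]      # keeps mature Q:P:F near 4:3:1
OMEGA_CTERM = "TIPHQGSVHPQHQLAHLEVMTSIALRTLPTMSNVAVL"      # cysteine-free

EPITOPES = {
    "DQ2.5-glia-α1a": "PFPQPQLPY",
    "DQ2.5-glia-α3": "FRPQQPYPQ",
    "19-residue-peptide": "LGQQQPFPPQQPYPQPQPF",
    "12-residue-peptide": "LGQGSFRPSQQN",
    "DQ8-glia-α1": "QGSFQPSQQ",
    "DQ2.5-glia-γ5": "QQPFPQQPQ",
    "DQ2.5-glia-γ2": "IQPQQPAQL",
    "hexa-QQFPQQ": "QQFPQQ",
}

#: preferred codon per residue; Q and R are drawn stochastically so that
#: CAG (stop-creatable) and CGA codons occur at realistic rates
PREFERRED_CODON = {
    "A": "GCT", "N": "AAT", "D": "GAT", "C": "TGT", "E": "GAA",
    "G": "GGT", "H": "CAT", "I": "ATT", "L": "CTT", "K": "AAA",
    "M": "ATG", "F": "TTT", "P": "CCT", "S": "TCT", "T": "ACT",
    "W": "TGG", "Y": "TAT", "V": "GTT",
}
SYNONYMOUS = {
    "A": ["GCT", "GCC", "GCA"], "R": ["CGT", "CGA", "CGC", "AGA"],
    "N": ["AAT", "AAC"], "D": ["GAT", "GAC"], "C": ["TGT", "TGC"],
    "E": ["GAA", "GAG"], "Q": ["CAA", "CAG"], "G": ["GGT", "GGC", "GGA"],
    "H": ["CAT", "CAC"], "I": ["ATT", "ATC", "ATA"],
    "L": ["CTT", "CTC", "CTA", "TTA", "TTG"], "K": ["AAA", "AAG"],
    "F": ["TTT", "TTC"], "P": ["CCT", "CCC", "CCA"],
    "S": ["TCT", "TCC", "TCA", "AGT"], "T": ["ACT", "ACC", "ACA"],
    "Y": ["TAT", "TAC"], "V": ["GTT", "GTC", "GTA"],
    "M": ["ATG"], "W": ["TGG"],
}

STAGES = ["5", "10", "15", "20", "25", "leaf"]


@dataclass
class SimConfig:
    """Study-condition knobs for the generator; defaults mirror the
    published family composition and RNA-Seq design."""

    n_alpha: int = 23
    n_gamma: int = 3
    n_omega: int = 2
    pseudogene_fraction: float = 12 / 28
    frameshift_fraction: float = 1 / 12     # of pseudogenes, one in twelve
    cga_rate: float = 0.08                  # rare CGA→TGA stop origin
    n_stop_range: tuple[int, int] = (1, 3)
    divergence_subs: int = 5                # synonymous codons changed per pseudogene
    n_duplicate_pairs: int = 1              # near-identical active α pairs
    duplicate_subs: int = 2
    template_snps: int = 4                  # gene-specific SNPs in unique domains

    qi_range: tuple[int, int] = (9, 33)     # residues: 27–99 bp
    qii_range: tuple[int, int] = (8, 16)
    gamma_iv_range: tuple[int, int] = (10, 25)
    alpha_units_range: tuple[int, int] = (4, 8)
    gamma_units_range: tuple[int, int] = (8, 14)
    omega_units_range: tuple[int, int] = (36, 48)
    polyq_caa_weight: float = 0.6           # CAA vs CAG inside polyQ tracts
    arg_cga_weight: float = 0.3             # CGA vs CGT for arginine

    alpha_group_weights: dict = field(
        default_factory=lambda: {"I": 0.10, "II": 0.45, "III": 0.25, "none": 0.20}
    )
    omega_class_weights: dict = field(
        default_factory=lambda: {"ARQ": 0.5, "ARE": 0.2, "ARH": 0.3}
    )
    gamma_epitope_rates: dict = field(
        default_factory=lambda: {"DQ2.5-glia-γ5": 0.4, "DQ2.5-glia-γ2": 0.3}
    )
    omega_epitope_rates: dict = field(default_factory=lambda: {"hexa-QQFPQQ": 0.4})
    alpha_19mer_rate: float = 0.4           # extra 19-mer in group I/III genes

    # expression model
    n_replicates: int = 3
    library_size_mean: float = 21.78e6
    library_size_sd: float = 1.5e6
    peak_rpkm_log_mean: float = float(np.log(15000.0))
    peak_rpkm_log_sd: float = 0.6
    peak_rpkm_bounds: tuple[float, float] = (3000.0, 40000.0)
    stage_multipliers: dict = field(
        default_factory=lambda: {"5": 0.001, "10": 0.5, "15": 1.0,
                                 "20": 0.5, "25": 1 / 6, "leaf": 0.0002}
    )
    stable_multiplier: float = 0.85         # 10/20 DPA level of stable genes
    stable_fraction: float = 0.3
    nb_dispersion: float = 0.05
    background_rpkm_max: float = 3.0        # pseudogenes and leaf

    # spot model
    spot_identity_threshold: float = 0.96   # protein identity merging spots
    spot_mw_jitter_kd: float = 0.3
    spot_pi_jitter: float = 0.05
    spot_peptides_range: tuple[int, int] = (5, 10)
    digest_min_len: int = 7
    digest_max_len: int = 30

    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        import yaml

        data = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**data)
        return cfg


@dataclass
class GeneTruth:
    gene_id: str
    gliadin_type: str
    status: str
    cds: str
    protein: str                                # conceptual translation, stops as *
    domains: dict                               # label -> [start, end], 1-based
    planted_epitopes: list                      # [name, 1-based protein start]
    stop_events: list = field(default_factory=list)        # [codon_index, origin]
    frameshift_events: list = field(default_factory=list)  # [cds_pos, kind, length]
    progenitor_id: str | None = None
    duplicate_of: str | None = None
    alpha_group: str | None = None
    omega_class: str | None = None


@dataclass
class FamilyTruth:
    genes: dict                                  # id -> GeneTruth

    def active_ids(self) -> list[str]:
        return [g for g, t in self.genes.items() if t.status == FULL_ORF]

    def to_json(self, path) -> None:
        Path(path).write_text(
            json.dumps({g: asdict(t) for g, t in self.genes.items()}, indent=1)
        )

    @classmethod
    def from_json(cls, path) -> "FamilyTruth":
        raw = json.loads(Path(path).read_text())
        return cls(genes={g: GeneTruth(**t) for g, t in raw.items()})


# ---------------------------------------------------------------------------
# codon-level construction


def _weighted_choice(rng: np.random.Generator, options: dict) -> str:
    keys = list(options)
    probs = np.array([options[k] for k in keys], dtype=float)
    return str(rng.choice(keys, p=probs / probs.sum()))


def reverse_translate(protein: str, rng: np.random.Generator,
                      caa_weight: float = 0.6, cga_weight: float = 0.3) -> str:
    """Codon-level synthesis; Q codons are CAA/CAG draws so C→T stop
    creation is possible at CAG sites, R codons occasionally CGA."""
    codons = []
    for aa in protein:
        if aa == "Q":
            codons.append("CAA" if rng.random() < caa_weight else "CAG")
        elif aa == "R":
            codons.append("CGA" if rng.random() < cga_weight else "CGT")
        else:
            codons.append(PREFERRED_CODON[aa])
    return "".join(codons)


def _assemble(parts: list[tuple[str, str]]) -> tuple[str, dict]:
    """Concatenate (label, seq) parts into a protein + 1-based domain map."""
    protein, domains, pos = [], {}, 1
    for label, seq in parts:
        domains[label] = [pos, pos + len(seq) - 1]
        protein.append(seq)
        pos += len(seq)
    return "".join(protein), domains


def _insert_interior(blocks: list[str], insert: str, rng: np.random.Generator) -> None:
    """Insert a block at an interior boundary (never first or last)."""
    idx = int(rng.integers(1, len(blocks))) if len(blocks) > 1 else 1
    blocks.insert(idx, insert)


def _planted_offsets(blocks: list[str], names: list[str]) -> dict[str, int]:
    """0-based offsets of planted epitope blocks, found by object identity
    (the inserted block IS the library string, units are distinct objects)."""
    out, pos = {}, 0
    for b in blocks:
        for name in names:
            if b is EPITOPES[name]:
                out[name] = pos
        pos += len(b)
    return out


def _build_alpha(rng: np.random.Generator, cfg: SimConfig):
    group = _weighted_choice(rng, cfg.alpha_group_weights)
    n_units = int(rng.integers(cfg.alpha_units_range[0], cfg.alpha_units_range[1] + 1))
    blocks = [ALPHA_REPEAT_UNITS[int(i)]
              for i in rng.integers(0, len(ALPHA_REPEAT_UNITS), size=n_units)]
    planted_names: list[str] = []

    def plant(name: str) -> None:
        _insert_interior(blocks, EPITOPES[name], rng)
        planted_names.append(name)
        # a P-starting unit right after ...PQLPY would assemble the
        # DQ2.5-glia-α2 sequence, which A-genome α gliadins lack
        idx = next(i for i, b in enumerate(blocks) if b is EPITOPES[name])
        if name == "DQ2.5-glia-α1a" and blocks[idx + 1].startswith("P"):
            blocks.insert(idx + 1, "QPYPQPQP")

    if group in ("II", "III"):
        plant("DQ2.5-glia-α1a")
        plant("DQ2.5-glia-α3")
    if group in ("I", "III") and rng.random() < cfg.alpha_19mer_rate:
        plant("19-residue-peptide")
    blocks.append(ALPHA_REPEAT_CLOSER)          # >=3 non-Q before the QI tract
    repetitive = "".join(blocks)
    rep_epitopes = _planted_offsets(blocks, planted_names)

    qi_len = int(rng.integers(cfg.qi_range[0], cfg.qi_range[1] + 1))
    qii_len = int(rng.integers(cfg.qii_range[0], cfg.qii_range[1] + 1))
    qi = ["Q"] * qi_len
    qii = ["Q"] * qii_len
    if group == "I":
        qi[int(rng.integers(2, qi_len - 2))] = "A"
    if group == "II":
        qii[int(rng.integers(2, qii_len - 2))] = "K"

    uii = ALPHA_UII
    if group == "I":  # restore DQ8-glia-α1 by the R→Q change at its position 5
        uii = uii[:_UII_DQ8_R_OFFSET] + "Q" + uii[_UII_DQ8_R_OFFSET + 1 :]

    protein, domains = _assemble(
        [
            ("signal", SIGNAL_ALPHA),
            ("repetitive", repetitive),
            ("QI", "".join(qi)),
            ("UI", ALPHA_UI),
            ("QII", "".join(qii)),
            ("UII", uii),
        ]
    )
    planted = [
        (name, domains["repetitive"][0] + off) for name, off in rep_epitopes.items()
    ]
    uii_start = domains["UII"][0]
    if group == "I":
        planted.append(("DQ8-glia-α1", uii_start + _UII_DQ8_OFFSET))
    else:
        planted.append(("12-residue-peptide", uii_start + _UII_12MER_OFFSET))
    return protein, domains, sorted(planted, key=lambda p: p[1]), {"alpha_group": group}


def _build_gamma(rng: np.random.Generator, cfg: SimConfig):
    n_units = int(rng.integers(cfg.gamma_units_range[0], cfg.gamma_units_range[1] + 1))
    blocks = [GAMMA_REPEAT_POOL[int(i)]
              for i in rng.integers(0, len(GAMMA_REPEAT_POOL), size=n_units)]
    planted_names = []
    for name, rate in cfg.gamma_epitope_rates.items():
        if rng.random() < rate:
            _insert_interior(blocks, EPITOPES[name], rng)
            planted_names.append(name)
    rep_epitopes = _planted_offsets(blocks, planted_names)
    iv_len = int(rng.integers(cfg.gamma_iv_range[0], cfg.gamma_iv_range[1] + 1))
    protein, domains = _assemble(
        [
            ("signal", SIGNAL_GAMMA),
            ("I", GAMMA_I),
            ("II", "".join(blocks)),
            ("III", GAMMA_III),
            ("IV", "Q" * iv_len),
            ("V", GAMMA_V),
        ]
    )
    planted = [(name, domains["II"][0] + off) for name, off in rep_epitopes.items()]
    return protein, domains, sorted(planted, key=lambda p: p[1]), {}


def _build_omega(rng: np.random.Generator, cfg: SimConfig):
    omega_class = _weighted_choice(rng, cfg.omega_class_weights)
    n_units = int(rng.integers(cfg.omega_units_range[0], cfg.omega_units_range[1] + 1))
    probs = np.array(OMEGA_REPEAT_WEIGHTS)
    blocks = [
        OMEGA_REPEAT_POOL[int(i)]
        for i in rng.choice(len(OMEGA_REPEAT_POOL), size=n_units, p=probs)
    ]
    planted_names = []
    for name, rate in cfg.omega_epitope_rates.items():
        if rng.random() < rate:
            _insert_interior(blocks, EPITOPES[name], rng)
            planted_names.append(name)
    rep_epitopes = _planted_offsets(blocks, planted_names)
    protein, domains = _assemble(
        [
            ("signal", SIGNAL_OMEGA),
            ("N-terminal", omega_class + OMEGA_NTERM_TAIL),
            ("repetitive", "".join(blocks)),
            ("C-terminal", OMEGA_CTERM),
        ]
    )
    planted = [
        (name, domains["repetitive"][0] + off) for name, off in rep_epitopes.items()
    ]
    return protein, domains, sorted(planted, key=lambda p: p[1]), {"omega_class": omega_class}


_BUILDERS = {ALPHA: _build_alpha, GAMMA: _build_gamma, OMEGA: _build_omega}

#: benign substitutions used to scatter gene-specific SNPs through the
#: non-repetitive template domains (never Q, C or a cleavage residue)
_SNP_MAP = {"S": "T", "T": "S", "I": "V", "V": "I", "E": "D",
            "D": "E", "N": "H", "H": "N", "A": "G", "G": "A"}
_SNP_DOMAINS = {ALPHA: ("UI", "UII"), GAMMA: ("I", "III", "V"),
                OMEGA: ("N-terminal", "C-terminal")}


def _apply_template_snps(
    protein: str,
    domains: dict,
    planted: list,
    gtype: str,
    rng: np.random.Generator,
    n_snps: int,
) -> str:
    """Scatter a few amino-acid substitutions through the unique/template
    domains so each family member carries gene-specific peptides, the way
    real family members differ by SNPs outside their repeats."""
    epitope_spans = [range(p, p + len(EPITOPES[n])) for n, p in planted if n in EPITOPES]
    positions = []
    for label in _SNP_DOMAINS[gtype]:
        s, e = domains[label]
        for i in range(s + 3, e - 2):
            if protein[i - 1] in _SNP_MAP and not any(i in sp for sp in epitope_spans):
                positions.append(i)
    if not positions:
        return protein
    picks = rng.choice(positions, size=min(n_snps, len(positions)), replace=False)
    chars = list(protein)
    for i in np.sort(picks):
        chars[int(i) - 1] = _SNP_MAP[chars[int(i) - 1]]
    return "".join(chars)


# ---------------------------------------------------------------------------
# pseudogenization


def _codons(cds: str) -> list[str]:
    return [cds[i : i + 3] for i in range(0, len(cds), 3)]


def _synonymous_divergence(
    codons: list[str], n_subs: int, protected: set[int], rng: np.random.Generator
) -> list[str]:
    """Swap codons for synonymous alternatives at n random positions."""
    candidates = [
        i
        for i, c in enumerate(codons)
        if i not in protected and i > 0 and len(SYNONYMOUS.get(_AA_OF.get(c, ""), [])) > 1
    ]
    if not candidates:
        return codons
    picks = rng.choice(len(candidates), size=min(n_subs, len(candidates)), replace=False)
    out = list(codons)
    for k in np.sort(picks):
        i = candidates[int(k)]
        aa = _AA_OF[out[i]]
        alts = [c for c in SYNONYMOUS[aa] if c != out[i]]
        out[i] = str(rng.choice(alts))
    return out


_AA_OF = {c: aa for aa, cods in SYNONYMOUS.items() for c in cods}
_AA_OF.update({c: aa for aa, c in PREFERRED_CODON.items()})

_STOP_OF = {"CAA": "TAA", "CAG": "TAG", "CGA": "TGA"}


def pseudogenize(
    progenitor_cds: str, cfg: SimConfig, rng: np.random.Generator
) -> tuple[str, str, list, list]:
    """Derive a pseudogene CDS from an active gene.

    Returns (cds, status, stop_events, frameshift_events).  Stops come
    from C→T at CAA/CAG (rarely CGA) codons; a minority of pseudogenes
    instead carry a single-base deletion (left-normalized position,
    reported against the progenitor).
    """
    codons = _codons(progenitor_cds)
    if rng.random() < cfg.frameshift_fraction:
        pos0 = int(rng.integers(30, len(progenitor_cds) - 30))
        pos0 = _left_normalize(progenitor_cds, pos0, 1)
        # keep the deletion's local context free of divergence so the gap
        # placement stays alignment-unambiguous
        protected = set(range(max(0, pos0 // 3 - 3), pos0 // 3 + 4))
        cds_div = "".join(
            _synonymous_divergence(codons, cfg.divergence_subs, protected, rng)
        )
        mutated = cds_div[:pos0] + cds_div[pos0 + 1 :]
        return mutated, PSEUDO_FRAMESHIFT, [], [[pos0 + 1, "deletion", 1]]

    q_sites = [i for i, c in enumerate(codons) if c in ("CAA", "CAG") and 0 < i < len(codons) - 1]
    n_stops = int(rng.integers(cfg.n_stop_range[0], cfg.n_stop_range[1] + 1))
    n_stops = min(n_stops, len(q_sites))
    picked = sorted(
        int(i) for i in rng.choice(q_sites, size=n_stops, replace=False)
    )
    cga_sites = [i for i, c in enumerate(codons) if c == "CGA" and 0 < i < len(codons) - 1]
    if cga_sites and len(picked) > 1 and rng.random() < cfg.cga_rate:
        picked = picked[:-1] + [int(rng.choice(cga_sites))]
        picked = sorted(set(picked))
    codons = _synonymous_divergence(codons, cfg.divergence_subs, set(picked), rng)
    events = []
    for i in picked:
        ref = codons[i]
        codons[i] = _STOP_OF[ref]
        events.append([i + 1, f"{ref}->{_STOP_OF[ref]}"])
    return "".join(codons), PSEUDO_STOP, events, []


def random_c_to_t(cds: str, rng: np.random.Generator) -> tuple[str, int]:
    """One uniform C→T transition; returns (mutated cds, 0-based position).

    Used to show that uniform C→T mutation pressure lands stops
    preferentially on glutamine codons in Q-rich sequences.
    """
    positions = [i for i, ch in enumerate(cds) if ch == "C"]
    if not positions:
        raise ValueError("sequence contains no C")
    pos = int(rng.choice(positions))
    return cds[:pos] + "T" + cds[pos + 1 :], pos


# ---------------------------------------------------------------------------
# family generation


def _translate_readthrough(cds: str) -> str:
    from Bio.Seq import Seq

    trimmed = cds[: len(cds) - len(cds) % 3]
    return str(Seq(trimmed).translate())


def generate_family(
    cfg: SimConfig | None = None, rng: np.random.Generator | None = None
) -> tuple[list[SequenceRecord], FamilyTruth]:
    """Generate a gliadin family FASTA-ready record list plus ground truth."""
    cfg = cfg or SimConfig()
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)

    plan: list[tuple[str, str]] = []
    for gtype, n, prefix in (
        (ALPHA, cfg.n_alpha, "Gli-alpha-"),
        (GAMMA, cfg.n_gamma, "Gli-gamma-"),
        (OMEGA, cfg.n_omega, "Gli-omega-"),
    ):
        statuses = rng.random(n) < cfg.pseudogene_fraction
        if n and statuses.all():
            statuses[0] = False                 # keep >=1 active per type
        for i in range(n):
            plan.append((f"{prefix}{i + 1:02d}", gtype, bool(statuses[i])))  # type: ignore[arg-type]

    truth: dict[str, GeneTruth] = {}
    actives_by_type: dict[str, list[str]] = {ALPHA: [], GAMMA: [], OMEGA: []}

    # pass 1: active genes
    for gene_id, gtype, is_pseudo in plan:
        if is_pseudo:
            continue
        protein, domains, planted, extra = _BUILDERS[gtype](rng, cfg)
        protein = _apply_template_snps(
            protein, domains, planted, gtype, rng, cfg.template_snps
        )
        cds = reverse_translate(protein, rng, cfg.polyq_caa_weight, cfg.arg_cga_weight)
        truth[gene_id] = GeneTruth(
            gene_id=gene_id,
            gliadin_type=gtype,
            status=FULL_ORF,
            cds=cds,
            protein=protein,
            domains=domains,
            planted_epitopes=[[n, p] for n, p in planted],
            **extra,
        )
        actives_by_type[gtype].append(gene_id)

    # optional near-identical active α pairs (ambiguous-spot substrate)
    dup_sub_map = {"P": "S", "S": "P", "Y": "F", "F": "Y"}
    made_pairs = 0
    for gene_id in list(actives_by_type[ALPHA]):
        if made_pairs >= cfg.n_duplicate_pairs or len(actives_by_type[ALPHA]) < 2:
            break
        source_id = actives_by_type[ALPHA][0]
        if gene_id == source_id:
            continue
        src = truth[source_id]
        rep_s, rep_e = src.domains["repetitive"]
        epitope_spans = [
            range(p, p + len(EPITOPES[n])) for n, p in src.planted_epitopes
        ]
        positions = [
            i
            for i in range(rep_s, rep_e + 1)
            if src.protein[i - 1] in dup_sub_map
            and not any(i in span for span in epitope_spans)
        ]
        picks = rng.choice(
            positions, size=min(cfg.duplicate_subs, len(positions)), replace=False
        )
        protein = list(src.protein)
        for i in np.sort(picks):
            protein[int(i) - 1] = dup_sub_map[protein[int(i) - 1]]
        protein = "".join(protein)
        cds = reverse_translate(protein, rng, cfg.polyq_caa_weight, cfg.arg_cga_weight)
        truth[gene_id] = GeneTruth(
            gene_id=gene_id,
            gliadin_type=ALPHA,
            status=FULL_ORF,
            cds=cds,
            protein=protein,
            domains={k: list(v) for k, v in src.domains.items()},
            planted_epitopes=[list(p) for p in src.planted_epitopes],
            duplicate_of=source_id,
            alpha_group=src.alpha_group,
        )
        made_pairs += 1

    # pass 2: pseudogenes as mutated near-copies of actives
    for gene_id, gtype, is_pseudo in plan:
        if not is_pseudo:
            continue
        progenitor_id = str(rng.choice(actives_by_type[gtype]))
        prog = truth[progenitor_id]
        cds, status, stop_events, fs_events = pseudogenize(prog.cds, cfg, rng)
        truth[gene_id] = GeneTruth(
            gene_id=gene_id,
            gliadin_type=gtype,
            status=status,
            cds=cds,
            protein=_translate_readthrough(cds),
            domains={k: list(v) for k, v in prog.domains.items()},
            planted_epitopes=[list(p) for p in prog.planted_epitopes],
            stop_events=stop_events,
            frameshift_events=fs_events,
            progenitor_id=progenitor_id,
            alpha_group=prog.alpha_group,
            omega_class=prog.omega_class,
        )

    ordered = {gid: truth[gid] for gid, _, _ in plan}
    records = [
        SequenceRecord(id=gid, sequence=t.cds, description=f"synthetic {t.gliadin_type}-gliadin CDS")
        for gid, t in ordered.items()
    ]
    return records, FamilyTruth(genes=ordered)


# ---------------------------------------------------------------------------
# expression counts


def generate_expression(
    truth: FamilyTruth, cfg: SimConfig, rng: np.random.Generator
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    """Counts + sample sheet + gene lengths emulating the RNA-Seq design.

    Active genes ramp up after 5 DPA, peak at 15 DPA and decline through
    25 DPA; pseudogenes and the flag leaf see only background.  Counts are
    negative-binomial around the RPKM-implied means.
    """
    genes = list(truth.genes)
    lengths = pd.Series({g: len(t.cds) for g, t in truth.genes.items()}, name="length")
    sample_rows = []
    for stage in STAGES:
        for rep in range(1, cfg.n_replicates + 1):
            lib = max(5e6, rng.normal(cfg.library_size_mean, cfg.library_size_sd))
            sample_rows.append(
                {
                    "sample": f"{stage}dpa_r{rep}" if stage != "leaf" else f"leaf_r{rep}",
                    "stage": stage,
                    "replicate": rep,
                    "library_size": int(lib),
                }
            )
    samples = pd.DataFrame(sample_rows)

    lo, hi = cfg.peak_rpkm_bounds
    peaks, stable_flags = {}, {}
    for g in genes:
        if truth.genes[g].status == FULL_ORF:
            peaks[g] = float(
                np.clip(rng.lognormal(cfg.peak_rpkm_log_mean, cfg.peak_rpkm_log_sd), lo, hi)
            )
            stable_flags[g] = bool(rng.random() < cfg.stable_fraction)
        else:
            peaks[g] = 0.0
            stable_flags[g] = False

    counts = np.zeros((len(genes), len(samples)), dtype=int)
    r = 1.0 / cfg.nb_dispersion
    for gi, g in enumerate(genes):
        active = truth.genes[g].status == FULL_ORF
        for si, srow in samples.iterrows():
            stage = srow["stage"]
            if active:
                mult = cfg.stage_multipliers[stage]
                if stable_flags[g] and stage in ("10", "20"):
                    mult = cfg.stable_multiplier
                target_rpkm = peaks[g] * mult
            else:
                target_rpkm = 0.0
            if stage == "leaf" or not active:
                target_rpkm += rng.uniform(0.2, cfg.background_rpkm_max)
            mean = target_rpkm * srow["library_size"] * lengths[g] / 1e9
            if mean <= 0:
                continue
            p = r / (r + mean)
            counts[gi, si] = int(rng.negative_binomial(r, p))
    counts_df = pd.DataFrame(counts, index=genes, columns=samples["sample"])
    return counts_df, samples, lengths


# ---------------------------------------------------------------------------
# 2-DE spots


def _protein_identity(a: str, b: str) -> float:
    d = edlib.align(a, b, mode="NW", task="distance")["editDistance"]
    return 1.0 - d / max(len(a), len(b))


def generate_spots(
    truth: FamilyTruth, cfg: SimConfig, rng: np.random.Generator
) -> tuple[list[SpotTableRow], dict[int, dict]]:
    """Spot table from the active proteins' physicochemistry and digests.

    Near-identical proteins merge into one ambiguous spot whose peptides
    are drawn from the shared digest; singleton spots carry at least one
    gene-exclusive peptide when the digest provides one.  Returns the spot
    rows plus {spot_id: {"genes": [...], "unique": bool}} ground truth.
    """
    actives = truth.active_ids()
    proteins = {g: truth.genes[g].protein for g in actives}

    # single-linkage clusters above the identity threshold
    clusters: list[list[str]] = []
    for g in actives:
        placed = False
        for cl in clusters:
            if any(
                _protein_identity(proteins[g], proteins[m]) >= cfg.spot_identity_threshold
                for m in cl
            ):
                cl.append(g)
                placed = True
                break
        if not placed:
            clusters.append([g])

    digests = {
        g: sorted(
            {
                p.sequence
                for p in chymotryptic_digest(
                    proteins[g], g, max_missed=2, min_len=cfg.digest_min_len
                )
                if len(p.sequence) <= cfg.digest_max_len
            }
        )
        for g in actives
    }

    def owners(pep: str) -> set[str]:
        return {g for g in actives if pep in proteins[g]}

    rows: list[SpotTableRow] = []
    spot_truth: dict[int, dict] = {}
    raw_volumes = rng.lognormal(0.0, 1.0, size=len(clusters))
    volumes = raw_volumes / raw_volumes.sum() * 100.0
    for spot_id, (cluster, vol) in enumerate(zip(clusters, volumes), start=1):
        members = sorted(cluster)
        pcs = [_physchem.physchem(proteins[g]) for g in members]
        mw = float(np.mean([p.mw_kd for p in pcs]) + rng.normal(0, cfg.spot_mw_jitter_kd))
        pi = float(np.mean([p.pi for p in pcs]) + rng.normal(0, cfg.spot_pi_jitter))
        n_peps = int(rng.integers(*cfg.spot_peptides_range))
        if len(members) == 1:
            g = members[0]
            exclusive = [p for p in digests[g] if owners(p) == {g}]
            shared = [p for p in digests[g] if p not in exclusive]
            chosen: list[str] = []
            if exclusive:
                chosen.append(str(rng.choice(exclusive)))
            pool = shared or digests[g]
            extra = rng.choice(pool, size=min(n_peps - len(chosen), len(pool)), replace=False)
            chosen.extend(str(p) for p in extra)
            unique = bool(exclusive)
        else:
            common = sorted(
                p for p in digests[members[0]] if all(p in proteins[m] for m in members)
            )
            # peptides seen in exactly the cluster members pin the group down;
            # fall back to member-shared, then to any member-0 peptide
            exact = [p for p in common if owners(p) == set(members)]
            pool = exact or common or digests[members[0]]
            take = rng.choice(pool, size=min(n_peps, len(pool)), replace=False)
            chosen = [str(p) for p in take]
            unique = False
        rows.append(
            SpotTableRow(
                spot_id=spot_id,
                percent_volume=round(float(vol), 4),
                mw_kd=round(max(mw, 1.0), 2),
                pi=round(min(max(pi, 3.0), 10.0), 2),
                peptides=chosen,
            )
        )
        spot_truth[spot_id] = {"genes": members, "unique": unique}
    return rows, spot_truth


# ---------------------------------------------------------------------------
# one-call dataset writer


def simulate_dataset(cfg: SimConfig, outdir) -> dict[str, Path]:
    """Write family.fasta, truth.json, counts.tsv, samples.tsv, spots.tsv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    records, truth = generate_family(cfg, rng)
    counts, samples, lengths = generate_expression(truth, cfg, rng)
    spots, spot_truth = generate_spots(truth, cfg, rng)

    paths = {
        "fasta": outdir / "family.fasta",
        "truth": outdir / "truth.json",
        "counts": outdir / "counts.tsv",
        "samples": outdir / "samples.tsv",
        "lengths": outdir / "gene_lengths.tsv",
        "spots": outdir / "spots.tsv",
        "spot_truth": outdir / "spot_truth.json",
    }
    write_fasta(records, paths["fasta"])
    truth.to_json(paths["truth"])
    counts.to_csv(paths["counts"], sep="\t", index_label="gene")
    samples.to_csv(paths["samples"], sep="\t", index=False)
    lengths.to_frame().to_csv(paths["lengths"], sep="\t", index_label="gene")
    write_spot_table(spots, paths["spots"])
    paths["spot_truth"].write_text(json.dumps(spot_truth, indent=1))
    return paths
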