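"""End-to-end orchestration: annotate a family, profile expression,
assign spots.  Each runner is a plain function returning DataFrames (and
optionally writing the TSV/GFF artifacts), so the stages compose from
Python as readily as from the command line."""

from __future__ import annotations

import warnings
from pathlib import Path

import pandas as pd

from . import domain_grammar, expression, motif_epitope, orf_core, physchem, proteomics
from .domain_grammar import ALPHA, GAMMA, OMEGA, UNKNOWN
from .seqio import (
    GeneTableRow,
    SequenceRecord,
    SpotTableRow,
    write_domain_gff,
)

_PREFIX_TYPES = (
    (("α", "alpha", "-a-"), ALPHA),
    (("γ", "gamma", "-g-"), GAMMA),
    (("ω", "omega", "-w-"), OMEGA),
)


def gene_type_from_name(name: str) -> str:
    low = name.lower()
    for tokens, gtype in _PREFIX_TYPES:
        if any(t in low for t in tokens):
            return gtype
    return UNKNOWN


def run_annotate(
    records: list[SequenceRecord],
    gene_table: list[GeneTableRow] | None = None,
    outdir: str | Path | None = None,
    signal_length: dict[str, int] | None = None,
    pka_set: str = "bjellqvist",
    mature: bool = False,
) -> dict:
    """Annotate a family of gliadin CDS records.

    Produces the gene catalogue (type, ORF status, lengths, cysteines),
    domain segmentations, epitope content and physicochemistry, plus a
    summary block of type/full-ORF totals.  Gene types come from the
    catalogue naming convention when a gene table is supplied, from
    sequence features otherwise.
    """
    sig_cfg = {**domain_grammar.DEFAULT_SIGNAL_LENGTH, **(signal_length or {})}
    table_types = {}
    if gene_table:
        table_types = {row.gene_name: gene_type_from_name(row.gene_name) for row in gene_table}

    # full-ORF panel for reference-based pseudogene analysis
    panel: dict[str, str] = {}
    for rec in records:
        if len(rec.sequence) % 3 == 0:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                trimmed = orf_core.trim_terminal_stop(rec.sequence)
                if "*" not in orf_core.translate_cds(trimmed):
                    panel[rec.id] = trimmed

    orf_results: list[orf_core.OrfResult] = []
    annotations: list[domain_grammar.ProteinAnnotation] = []
    hits_per_gene: dict[str, list[motif_epitope.EpitopeHit]] = {}
    catalogue_rows = []
    physchem_rows = []
    library = motif_epitope.load_epitope_library()

    for rec in records:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = orf_core.classify_orf(rec.sequence, panel, gene_id=rec.id)
        orf_results.append(res)
        gtype = table_types.get(rec.id) or gene_type_from_name(rec.id)
        if gtype == UNKNOWN:
            try:
                gtype = domain_grammar.infer_gliadin_type(res.protein)
            except ValueError:
                gtype = UNKNOWN

        ann = None
        if gtype != UNKNOWN:
            ann = domain_grammar.segment_domains(
                res.protein, gtype, gene_id=rec.id, signal_length=sig_cfg[gtype]
            )
            annotations.append(ann)
        hits = motif_epitope.scan_epitopes(res.protein, library, ann)
        hits_per_gene[rec.id] = hits
        profile = motif_epitope.cysteine_profile(res.protein, ann)

        full = res.status == orf_core.FULL_ORF
        catalogue_rows.append(
            {
                "gene": rec.id,
                "type": gtype,
                "status": res.status,
                "fragment_length": len(rec.sequence),
                "predicted_aa_length": len(res.protein) if full else "pseudo",
                "n_cysteines": profile.total,
                "n_internal_stops": len(res.stop_events),
                "stop_origins": ";".join(e.origin for e in res.stop_events),
                "n_epitope_hits": len(hits),
            }
        )
        if full:
            pc = physchem.physchem(
                res.protein,
                pka_set,
                mature_start=ann.mature_start if (mature and ann) else None,
            )
            physchem_rows.append(
                {
                    "gene": rec.id,
                    "mw_kd": round(pc.mw_kd, 2),
                    "pi": round(pc.pi, 2),
                    "pka_set": pka_set,
                    "sequence_scope": "mature" if mature else "full",
                }
            )

    catalogue = pd.DataFrame(catalogue_rows)
    summary = {
        "n_genes": len(records),
        "n_alpha": int((catalogue["type"] == ALPHA).sum()),
        "n_gamma": int((catalogue["type"] == GAMMA).sum()),
        "n_omega": int((catalogue["type"] == OMEGA).sum()),
        "n_full_orf": int((catalogue["status"] == orf_core.FULL_ORF).sum()),
        "n_pseudo": int((catalogue["status"] != orf_core.FULL_ORF).sum()),
    }
    out = {
        "catalogue": catalogue,
        "summary": summary,
        "orf": orf_core.orf_report(orf_results),
        "annotations": annotations,
        "epitopes": motif_epitope.epitope_table(
            [r.id for r in records], hits_per_gene, library
        ),
        "physchem": pd.DataFrame(physchem_rows),
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        catalogue.to_csv(outdir / "catalogue.tsv", sep="\t", index=False)
        out["orf"].to_csv(outdir / "orf_status.tsv", sep="\t", index=False)
        out["epitopes"].to_csv(outdir / "epitopes.tsv", sep="\t")
        out["physchem"].to_csv(outdir / "physchem.tsv", sep="\t", index=False)
        write_domain_gff(annotations, outdir / "domains.gff3")
    return out


def run_expression(
    counts: pd.DataFrame,
    samples: pd.DataFrame,
    gene_lengths: pd.Series | dict,
    threshold: float = expression.DEFAULT_EXPRESSION_THRESHOLD,
    stability_fraction: float = expression.DEFAULT_STABILITY_FRACTION,
    outdir: str | Path | None = None,
) -> dict:
    """RPKM matrix, stage means, expressed set, profile flags and the
    max/min fold spread at each grain stage."""
    cm = expression.CountMatrix(counts=counts, samples=samples)
    rpkm_df = expression.rpkm_matrix(cm, gene_lengths)
    means = expression.stage_means(rpkm_df, samples)
    expressed = expression.classify_expressed(means, threshold)
    profiles = expression.profile_table(means, threshold, stability_fraction)
    folds = {}
    if len(expressed) >= 2:
        for stage in expression.GRAIN_STAGES:
            if stage in means.columns:
                hi, lo, ratio = expression.fold_summary(means, stage, expressed)
                folds[stage] = {"max_gene": hi, "min_gene": lo, "ratio": ratio}
    out = {
        "rpkm": rpkm_df,
        "stage_means": means,
        "expressed": expressed,
        "profiles": profiles,
        "folds": folds,
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        rpkm_df.to_csv(outdir / "rpkm.tsv", sep="\t", index_label="gene")
        means.to_csv(outdir / "stage_means.tsv", sep="\t", index_label="gene")
        profiles.to_csv(outdir / "profiles.tsv", sep="\t")
    return out


def run_proteomics(
    spots: list[SpotTableRow],
    proteome: dict[str, str] | None = None,
    outdir: str | Path | None = None,
) -> dict:
    """Assign spots to genes and aggregate percent volumes.

    Spots carrying peptide lists are assigned by peptide evidence against
    the supplied proteome; spots without peptides fall back to the
    table's own gene column (grouped by spot id).
    """
    assignments: dict[int, proteomics.SpotAssignment] = {}
    if proteome:
        peptides_by_spot: dict[int, list[str]] = {}
        for row in spots:
            if row.peptides:
                peptides_by_spot.setdefault(row.spot_id, []).extend(row.peptides)
        for spot_id, peps in peptides_by_spot.items():
            assignments[spot_id] = proteomics.assign_spot(spot_id, peps, proteome)
    volumes = proteomics.aggregate_volumes(spots, assignments or None)
    out = {
        "assignments": assignments,
        "assignment_table": proteomics.assignment_table(assignments)
        if assignments
        else pd.DataFrame(),
        "volumes": volumes,
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        if assignments:
            out["assignment_table"].to_csv(
                outdir / "spot_assignments.tsv", sep="\t", index=False
            )
        pd.DataFrame(
            sorted(volumes["per_class"].items()), columns=["class", "percent_volume"]
        ).to_csv(outdir / "class_volumes.tsv", sep="\t", index=False)
    return out


def run_report(annotate_out: dict, expression_out: dict | None = None) -> pd.DataFrame:
    """Join the per-stage TSVs into one gene-centric summary table."""
    report = annotate_out["catalogue"].set_index("gene")
    if not annotate_out["physchem"].empty:
        report = report.join(
            annotate_out["physchem"].set_index("gene")[["mw_kd", "pi"]]
        )
    if expression_out is not None:
        report = report.join(
            expression_out["profiles"][["peak_stage", "expressed", "stable"]]
        )
    return report.reset_index()
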