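"""RPKM expression profiles across grain development.

Counts are uniquely-mapped read tallies per gene per library; the design
is five grain stages (5, 10, 15, 20, 25 days post-anthesis) plus a flag
leaf control, three replicates each.  A gene is called expressed when any
grain-stage mean RPKM clears the threshold (1000 by default); the leaf is
deliberately excluded so the criterion captures endosperm expression.  A
profile is "stable" when the 10- and 20-DPA means both exceed 70% of the
15-DPA peak.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

GRAIN_STAGES = ["5", "10", "15", "20", "25"]
LEAF_STAGE = "leaf"
ALL_STAGES = GRAIN_STAGES + [LEAF_STAGE]

DEFAULT_EXPRESSION_THRESHOLD = 1000.0
DEFAULT_STABILITY_FRACTION = 0.70


@dataclass
class CountMatrix:
    """gene x sample read counts plus the sample sheet.

    ``samples`` needs columns sample/stage/replicate/library_size; counts
    columns must match the sample names.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(self.counts.columns) - set(self.samples["sample"])
        if missing:
            raise ValueError(f"samples sheet missing columns: {sorted(missing)}")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")
        sizes = self.samples.set_index("sample")["library_size"]
        for col in self.counts.columns:
            if sizes[col] < self.counts[col].sum():
                raise ValueError(f"{col}: library size below column sum")

    @property
    def stages(self) -> pd.Series:
        return self.samples.set_index("sample")["stage"].astype(str)


@dataclass
class StageProfile:
    gene: str
    stage_means: dict[str, float]
    peak_stage: str
    expressed: bool
    stable: bool


def rpkm(count: float, library_size: float, gene_length_bp: float) -> float:
    """Reads per kilobase of gene per million mapped reads: C·10⁹/(N·L)."""
    if library_size <= 0:
        raise ValueError("library size must be positive")
    if gene_length_bp <= 0:
        raise ValueError("gene length must be positive")
    return count * 1e9 / (library_size * gene_length_bp)


def rpkm_matrix(cm: CountMatrix, gene_lengths: dict[str, float] | pd.Series) -> pd.DataFrame:
    """gene x sample RPKM values; lengths are the cloned fragment lengths."""
    lengths = pd.Series(gene_lengths).reindex(cm.counts.index)
    if lengths.isna().any():
        missing = lengths[lengths.isna()].index.tolist()
        raise ValueError(f"missing gene lengths for {missing}")
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    sizes = cm.samples.set_index("sample")["library_size"]
    out = cm.counts.astype(float).copy()
    for col in out.columns:
        out[col] = out[col] * 1e9 / (sizes[col] * lengths)
    return out


def stage_means(
    rpkm_df: pd.DataFrame, samples: pd.DataFrame, agg: str = "mean"
) -> pd.DataFrame:
    """Collapse replicates to per-stage values (mean by default)."""
    stages = samples.set_index("sample")["stage"].astype(str)
    grouped = rpkm_df.T.groupby(stages.reindex(rpkm_df.columns))
    means = grouped.mean().T if agg == "mean" else grouped.median().T
    order = [s for s in ALL_STAGES if s in means.columns]
    return means[order]


def classify_expressed(
    means: pd.DataFrame, threshold: float = DEFAULT_EXPRESSION_THRESHOLD
) -> set[str]:
    """Genes whose mean RPKM clears the threshold at any grain stage.

    Leaf samples are excluded: a gene detected only in leaf is not called
    expressed under the endosperm criterion.
    """
    grain = [s for s in GRAIN_STAGES if s in means.columns]
    if not grain:
        raise ValueError("no grain-stage columns present")
    mask = (means[grain] > threshold).any(axis=1)
    return set(means.index[mask])


def characterize_profile(
    gene: str,
    means: dict[str, float] | pd.Series,
    threshold: float = DEFAULT_EXPRESSION_THRESHOLD,
    stability_fraction: float = DEFAULT_STABILITY_FRACTION,
) -> StageProfile:
    """Peak stage, expressed flag and grain-filling stability for one gene."""
    means = dict(pd.Series(means).items())
    missing = [s for s in GRAIN_STAGES if s not in means]
    if missing:
        raise ValueError(f"{gene}: missing grain stages {missing}")
    grain = {s: means[s] for s in GRAIN_STAGES}
    peak = max(GRAIN_STAGES, key=lambda s: grain[s])
    expressed = any(v > threshold for v in grain.values())
    ref = grain["15"]
    stable = (
        ref > 0
        and grain["10"] > stability_fraction * ref
        and grain["20"] > stability_fraction * ref
    )
    return StageProfile(
        gene=gene,
        stage_means=means,
        peak_stage=peak,
        expressed=expressed,
        stable=stable,
    )


def fold_summary(
    means: pd.DataFrame, stage: str, expressed: set[str]
) -> tuple[str, str, float]:
    """Max/min fold spread among expressed genes at one stage.

    Returns (gene with highest mean, gene with lowest, max/min ratio to
    2 decimals).
    """
    genes = [g for g in means.index if g in expressed]
    if len(genes) < 2:
        raise ValueError("need at least two expressed genes")
    vals = means.loc[genes, stage]
    hi, lo = vals.idxmax(), vals.idxmin()
    if vals[lo] == 0:
        raise ValueError("minimum stage mean is zero")
    return hi, lo, round(float(vals[hi] / vals[lo]), 2)


def profile_table(
    means: pd.DataFrame,
    threshold: float = DEFAULT_EXPRESSION_THRESHOLD,
    stability_fraction: float = DEFAULT_STABILITY_FRACTION,
) -> pd.DataFrame:
    """Stage means with expressed/peak/stable flags, one row per gene."""
    rows = []
    for gene in means.index:
        p = characterize_profile(gene, means.loc[gene], threshold, stability_fraction)
        row = {"gene": gene, **{f"mean_{s}": p.stage_means.get(s, np.nan) for s in ALL_STAGES}}
        row.update(
            peak_stage=p.peak_stage, expressed=p.expressed, stable=p.stable
        )
        rows.append(row)
    return pd.DataFrame(rows).set_index("gene")


def load_count_matrix(counts_path, samples_path) -> CountMatrix:
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    samples = pd.read_csv(samples_path, sep="\t", dtype={"stage": str})
    return CountMatrix(counts=counts, samples=samples)
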