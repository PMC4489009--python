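import warnings
from types import SimpleNamespace

import numpy as np
import pytest

from gliadinkit import expression as ex
from gliadinkit import synthetic as syn


@pytest.fixture(scope="session")
def family():
    """One seeded synthetic family with counts and spots, shared across tests."""
    cfg = syn.SimConfig(seed=42)
    rng = np.random.default_rng(42)
    records, truth = syn.generate_family(cfg, rng)
    counts, samples, lengths = syn.generate_expression(truth, cfg, rng)
    spots, spot_truth = syn.generate_spots(truth, cfg, rng)
    return SimpleNamespace(
        cfg=cfg,
        records=records,
        truth=truth,
        counts=counts,
        samples=samples,
        lengths=lengths,
        spots=spots,
        spot_truth=spot_truth,
        actives=set(truth.active_ids()),
        proteins={g: truth.genes[g].protein for g in truth.active_ids()},
    )


@pytest.fixture(scope="session")
def stage_means_df(family):
    cm = ex.CountMatrix(counts=family.counts, samples=family.samples)
    rpkm = ex.rpkm_matrix(cm, family.lengths)
    return ex.stage_means(rpkm, family.samples)


@pytest.fixture(autouse=True)
def _quiet_translation_warnings():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        yield


def random_protein(rng: np.random.Generator, length: int,
                   alphabet: str = "ACDEFGHIKLMNPQRSTVWY") -> str:
    return "".join(alphabet[i] for i in rng.integers(0, len(alphabet), size=length))
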