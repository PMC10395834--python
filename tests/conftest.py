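import numpy as np
import pandas as pd
import pytest

from micromr.gwas_io import HarmonizedInstrumentSet, SummaryDataset


def make_dataset(trait_id="trait", trait_type="exposure", rows=None):
    """Small hand-written summary dataset for unit tests."""
    if rows is None:
        rows = [
            ("rs1", "1", 1000, "A", "G", 0.3, 0.30, 0.02, 1e-50, 10000),
            ("rs2", "1", 2_000_000, "C", "T", 0.4, 0.20, 0.02, 1e-20, 10000),
            ("rs3", "2", 1000, "G", "C", 0.2, -0.25, 0.02, 1e-30, 10000),
        ]
    table = pd.DataFrame(
        rows,
        columns=[
            "variant_id", "chrom", "pos", "effect_allele", "other_allele",
            "eaf", "beta", "se", "pval", "n",
        ],
    )
    return SummaryDataset(trait_id, trait_type, table)


def make_instruments(bx, sx, by, sy, exposure_id="exp", outcome_id="out"):
    bx = np.asarray(bx, float)
    table = pd.DataFrame(
        dict(
            variant_id=[f"rs{i}" for i in range(len(bx))],
            beta_x=bx,
            se_x=np.broadcast_to(np.asarray(sx, float), bx.shape).copy(),
            beta_y=np.asarray(by, float),
            se_y=np.broadcast_to(np.asarray(sy, float), bx.shape).copy(),
            eaf=np.full(len(bx), 0.3),
            f_stat=(bx / np.broadcast_to(np.asarray(sx, float), bx.shape)) ** 2,
        )
    )
    return HarmonizedInstrumentSet(
        exposure_id, outcome_id, table, pd.DataFrame(columns=["variant_id", "reason"])
    )


@pytest.fixture
def toy_dataset():
    return make_dataset()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
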