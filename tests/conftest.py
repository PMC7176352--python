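import numpy as np
import pandas as pd
import pytest

from wbcmr.instruments import HarmonizedInstrument, harmonize
from wbcmr.simgen import SimTruth, simulate_sumstats
from wbcmr.sumstats_io import SumstatsTable


def make_table(rows, trait="trait"):
    """Build a SumstatsTable from dicts with defaults filled in."""
    defaults = {"chrom": "1", "pos": 1_000_000, "effect_allele": "A",
                "other_allele": "G", "eaf": 0.3, "beta": 0.1, "se": 0.01,
                "pvalue": 1e-10, "n": 100_000.0}
    full = []
    for i, r in enumerate(rows):
        d = dict(defaults)
        d.setdefault("rsid", f"rs{i+1}")
        d.update(r)
        full.append(d)
    return SumstatsTable(trait, pd.DataFrame(full))


def make_instruments(b_ratios, s_ratios, beta_x=1.0, se_x=1e-6):
    """Harmonized instruments whose Wald ratios/SEs equal the given arrays."""
    return [
        HarmonizedInstrument(rsid=f"rs{i+1}", beta_x=beta_x, se_x=se_x,
                             beta_y=b * beta_x, se_y=s * abs(beta_x))
        for i, (b, s) in enumerate(zip(b_ratios, s_ratios))
    ]


def simulate_harmonized(**kwargs):
    """Generate a paired scan and harmonize it; returns (instruments, truth)."""
    exposure, outcome, _, truth = simulate_sumstats(SimTruth(**kwargs))
    return harmonize(exposure, outcome), truth


@pytest.fixture(scope="session")
def clean_instruments():
    """50 strong instruments, true causal effect 0.2, no pleiotropy."""
    h, truth = simulate_harmonized(theta=0.2, n_snps=50, seed=7)
    return h, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
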