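import numpy as np
import pandas as pd
import pytest

import methylcmp as m


@pytest.fixture(scope="session")
def small_cfg() -> m.SimConfig:
    """300 kb single-chromosome study, enough for every descriptive check."""
    return m.SimConfig(
        seed=7, genome=m.GenomeParams(n_chroms=1, chrom_length_bp=300_000)
    )


@pytest.fixture(scope="session")
def small_sim(small_cfg):
    return m.simulate_methylome_pair(small_cfg)


def make_bins(rows) -> pd.DataFrame:
    """BinTable from (chrom, start, context, n_meth, n_unmeth, n_covered)."""
    df = pd.DataFrame(
        rows,
        columns=["chrom", "start", "context", "n_meth_sum", "n_unmeth_sum",
                 "n_covered_sites"],
    )
    df["end"] = df["start"] + 100
    return df[["chrom", "start", "end", "context", "n_meth_sum", "n_unmeth_sum",
               "n_covered_sites"]]


def make_calls(rows) -> pd.DataFrame:
    """Call table from (chrom, pos, strand, context, n_meth, n_unmeth)."""
    return pd.DataFrame(
        rows,
        columns=["chrom", "pos", "strand", "context", "n_meth", "n_unmeth"],
    )


def flat_truth(n_sites: int, p: float, context: str = "CHG") -> pd.DataFrame:
    """Truth table of n identical sites with methylation probability p."""
    return pd.DataFrame(
        {
            "chrom": "chr1",
            "pos": np.arange(n_sites) * 3,
            "strand": "+",
            "context": context,
            "compartment": "intergenic",
            "p_true": p,
        }
    )
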