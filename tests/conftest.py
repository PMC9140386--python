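import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from bsamap import CausalLocus, ChromSpec, GenomeSpec

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def default_genome() -> GenomeSpec:
    return GenomeSpec.default()


@pytest.fixture(scope="session")
def small_genome() -> GenomeSpec:
    """One 5-Mb chromosome of 100 cM: fast single-chromosome experiments."""
    return GenomeSpec((ChromSpec("chr1", 5_000_000, 100.0),))


@pytest.fixture(scope="session")
def small_causal(small_genome) -> CausalLocus:
    return CausalLocus("chr1", 2_500_000, "G", "A")


def make_sites(rows) -> pd.DataFrame:
    """Site-count table from (chrom, pos, mut_ref, mut_alt, wt_ref, wt_alt)."""
    from bsamap.simulate import SITE_COLUMNS

    if not rows:
        return pd.DataFrame(
            {c: pd.Series(dtype=(str if c in ("chrom", "ref", "alt") else int))
             for c in SITE_COLUMNS}
        )
    return pd.DataFrame(
        [
            {
                "chrom": chrom,
                "pos": pos,
                "ref": "G",
                "alt": "A",
                "mut_ref": mr,
                "mut_alt": ma,
                "wt_ref": wr,
                "wt_alt": wa,
            }
            for chrom, pos, mr, ma, wr, wa in rows
        ]
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
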