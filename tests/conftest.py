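import numpy as np
import pandas as pd
import pytest

from tmbstrat import FilterConfig, PanelDefinition, VariantRecord


@pytest.fixture(scope="session")
def mb_panel() -> PanelDefinition:
    """One-interval panel of exactly 1 Mb on chr1 ([0, 1e6))."""
    return PanelDefinition(
        pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [1_000_000]})
    )


@pytest.fixture
def filter_config() -> FilterConfig:
    return FilterConfig()


def make_variant(**overrides) -> VariantRecord:
    """Deep, strand-balanced somatic missense variant that passes all filters."""
    fields = dict(
        chrom="chr1",
        pos=500,
        ref="A",
        alt="T",
        tumor_ref=50,
        tumor_alt=50,
        normal_ref=100,
        normal_alt=0,
        alt_fwd=25,
        alt_rev=25,
        consequence="missense",
        popdb_count=0,
        known_germline=False,
        zygosity_call="somatic",
        deleterious_score=0.9,
    )
    fields.update(overrides)
    return VariantRecord(**fields)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
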