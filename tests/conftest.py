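import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from plastcomp import simulate_family, simulate_plastome


@pytest.fixture(scope="session")
def small_plastome():
    """Desk-scale quadripartite genome with planted truth (seed 42)."""
    return simulate_plastome(
        lsc_len=5000, ir_len=800, ssc_len=700, n_ssrs=5, n_compound=1,
        n_repeats=4, n_genes=6, junction_overlap=250, seed=42,
    )


@pytest.fixture(scope="session")
def midsize_plastome():
    """A larger fixture where every planted element class is populated."""
    return simulate_plastome(
        lsc_len=30_000, ir_len=6_000, ssc_len=4_000, n_ssrs=15,
        n_compound=2, n_repeats=12, n_genes=20, junction_overlap=484,
        seed=11,
    )


@pytest.fixture(scope="session")
def hotspot_family():
    """Aligned family with a 10x mutational hotspot on columns 2000-2800."""
    return simulate_family(
        ancestor_len=10_000, n_taxa=8, hotspot_spec=[(2000, 2800, 10.0)],
        seed=7,
    )
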