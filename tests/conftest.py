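"""Shared fixtures: the synthetic study community and one full analysis run.

The community is the package's standard study condition: ten 50-kb genomes
(three congeneric pairs at ~95% identity), five sister-taxon decoys, a
complete NsiI+NlaIII double digest with RE1::RE2 fragments >= 64 bp, and
error-free reads at abundances log-spaced over three orders of magnitude.
Built once per session; several acceptance-level tests share it.
"""
from __future__ import annotations

import pytest

from diagtax.align import build_reference_index
from diagtax.binning import BinningConfig
from diagtax.pipeline import classify_and_profile
from diagtax.simulate import make_mock_community, simulate_reads

COMMUNITY_SEED = 1
SIM_SEED = 2
TOTAL_READS = 50_000


@pytest.fixture(scope="session")
def mock():
    return make_mock_community(seed=COMMUNITY_SEED)


@pytest.fixture(scope="session")
def sim(mock):
    """Error-free complete-digest RE1::RE2 reads from the community."""
    return simulate_reads(
        mock.community, "complete_digest", total_reads=TOTAL_READS,
        scheme="RE1::RE2", min_fragment_len=64, seed=SIM_SEED,
    )


@pytest.fixture(scope="session")
def full_index(mock):
    """Reference over the community genomes plus the five decoys."""
    return build_reference_index(mock.all_records, mock.taxid_map)


@pytest.fixture(scope="session")
def analysis(sim, full_index, mock):
    """One full classify + profile + cross-rank-validate run."""
    return classify_and_profile(sim.reads, full_index, mock.tree, BinningConfig())
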