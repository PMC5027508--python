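"""Shared fixtures: anchors, libraries and small synthetic inputs."""
from __future__ import annotations

import pytest

from csb2scan.variant_scanner import AnchorPair, build_search_strings


@pytest.fixture(scope="session")
def rcrs_anchors() -> AnchorPair:
    """The packaged reference-derived anchor configuration."""
    return AnchorPair.packaged()


@pytest.fixture(scope="session")
def toy_anchors() -> AnchorPair:
    """Arbitrary synthetic anchors satisfying the non-G boundary invariant."""
    return AnchorPair(
        upstream_flank="ATTCGATCGT",
        downstream_flank="CATTCGGATA",
        upstream_extension="TTACGTACGTACTA",
        downstream_extension="CATGATCTAGGACT",
    )


@pytest.fixture(scope="session")
def a_library(rcrs_anchors):
    """Adenine-interrupted 12x12 library plus continuous G1-G24."""
    return build_search_strings(
        rcrs_anchors,
        m_range=(1, 12),
        n_range=(1, 12),
        interrupt_set=("A",),
        continuous_range=(1, 24),
    )


@pytest.fixture(scope="session")
def full_library(rcrs_anchors):
    """All three interrupting bases plus continuous tracts."""
    return build_search_strings(
        rcrs_anchors,
        m_range=(1, 12),
        n_range=(1, 12),
        interrupt_set=("A", "C", "T"),
        continuous_range=(1, 24),
    )
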