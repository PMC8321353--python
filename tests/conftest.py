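"""Shared fixtures: small analytic meshes and desk-scale synthetic sites.

Synthetic channels use 40 boundary segments and 4 floor rings, keeping every
fixture well under 2000 faces so the Monte-Carlo cross-checks stay fast.
"""

import logging

import numpy as np
import pytest

from reconsim.mesh_io import ChannelSpec, TriangleMesh, make_channel_site

# depth-tie warnings from symmetric constellations are expected in bulk runs
logging.getLogger("reconsim.visibility").setLevel(logging.ERROR)

FIXTURE_KW = dict(segments=40, bottom_rings=4, seed=3)


def square_plate(half: float = 10.0, z: float = 0.0, tag: str = "plate") -> TriangleMesh:
    v = np.array(
        [[-half, -half, z], [half, -half, z], [half, half, z], [-half, half, z]]
    )
    return TriangleMesh(
        vertices=v,
        faces=[[0, 1, 2], [0, 2, 3]],
        tags=np.array([tag, tag], dtype=object),
    )


@pytest.fixture(scope="session")
def plate() -> TriangleMesh:
    """A 20 x 20 mm upward-facing plate in the focal plane."""
    return square_plate()


@pytest.fixture(scope="session")
def stacked_plates() -> TriangleMesh:
    """A 30 x 30 mm base plate with a 16 x 16 mm plate 20 mm above it."""
    lower = square_plate(15.0, 0.0, "lower")
    upper = square_plate(8.0, 20.0, "upper")
    return TriangleMesh(
        vertices=np.vstack([lower.vertices, upper.vertices]),
        faces=np.vstack([lower.faces, upper.faces + 4]),
        tags=np.concatenate([lower.tags, upper.tags]),
    )


@pytest.fixture(scope="session")
def empty_channel() -> TriangleMesh:
    return make_channel_site(ChannelSpec(anatomy="none", **FIXTURE_KW))


@pytest.fixture(scope="session")
def relief_channel() -> TriangleMesh:
    return make_channel_site(ChannelSpec(anatomy="flat_relief", **FIXTURE_KW))


@pytest.fixture(scope="session")
def artery_channel() -> TriangleMesh:
    return make_channel_site(ChannelSpec(anatomy="spanning_artery", **FIXTURE_KW))


@pytest.fixture(scope="session")
def elliptical_channel() -> TriangleMesh:
    return make_channel_site(
        ChannelSpec(cross_section="elliptical", anatomy="flat_relief", **FIXTURE_KW)
    )
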