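import numpy as np
import pytest

from csa_aging.surface import _hex_axial_coords, build_hex_mesh


@pytest.fixture(scope="session")
def mesh5():
    """Two-hemisphere hex lattice with 5 rings (91 vertices per hemisphere)."""
    return build_hex_mesh(5)


@pytest.fixture(scope="session")
def mesh9():
    """Larger lattice whose central region has many complete 4-ring vertices."""
    return build_hex_mesh(9)


@pytest.fixture(scope="session")
def center5():
    """Index of the central (fully interior) left-hemisphere vertex of mesh5."""
    return _hex_axial_coords(5).index((0, 0))


def interior_vertices(rings: int, margin: int) -> np.ndarray:
    """Left-hemisphere vertices whose `margin`-ring neighborhood is complete."""
    ax = _hex_axial_coords(rings)
    return np.array(
        [
            i
            for i, (q, r) in enumerate(ax)
            if max(abs(q), abs(r), abs(q + r)) <= rings - margin
        ]
    )
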