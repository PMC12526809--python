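import numpy as np
import pytest

from posturehrv import Params


@pytest.fixture
def params():
    return Params()


@pytest.fixture
def posture_oracle():
    """Literal, independent implementation of the angle rules for one vector."""

    def oracle(v):
        v = np.asarray(v, dtype=float)
        v = v / np.linalg.norm(v)
        ex, ey, ez = np.eye(3)
        tx = np.degrees(np.arccos(np.clip(v @ ex, -1, 1)))
        ty = np.degrees(np.arccos(np.clip(v @ ey, -1, 1)))
        tz = np.degrees(np.arccos(np.clip(v @ ez, -1, 1)))
        if not (84 - 36 <= tx <= 84 + 36):
            return "non_lying"
        if ty < 65:
            return "left_lateral"
        if ty > 111:
            return "right_lateral"
        return "supine" if tz < 60 else "prone"

    return oracle


@pytest.fixture
def sphere_grid():
    """Unit vectors on a 2-degree spherical grid, off the decision boundaries."""
    thetas = np.arange(1.0, 180.0, 2.0)
    phis = np.arange(0.0, 360.0, 2.0)
    tt, pp = np.meshgrid(np.radians(thetas), np.radians(phis), indexing="ij")
    vecs = np.column_stack([
        np.cos(tt).ravel(),
        (np.sin(tt) * np.cos(pp)).ravel(),
        (np.sin(tt) * np.sin(pp)).ravel(),
    ])
    # exclude vectors within 0.5 deg of any threshold angle
    ax = np.degrees(np.arccos(np.clip(vecs, -1, 1)))
    margins = np.concatenate([
        np.abs(ax[:, [0]] - np.array([[48.0, 120.0]])),
        np.abs(ax[:, [1]] - np.array([[65.0, 111.0]])),
        np.abs(ax[:, [2]] - np.array([[60.0]])),
    ], axis=1)
    return vecs[margins.min(axis=1) > 0.5]
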