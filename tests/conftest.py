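import numpy as np
import pytest

import orgwound as ow


@pytest.fixture(scope="session")
def small_spec():
    """A quick-to-render organoid used by several imaging tests."""
    return ow.OrganoidSpec(n_cells=40, radius_um=50.0, n_frames=3, seed=11)


@pytest.fixture(scope="session")
def rendered_organoid(small_spec):
    """(truth, clean stack) for the small organoid; rendered once per session."""
    truth = ow.simulate_timelapse(ow.make_organoid(small_spec), ow.MotionSpec())
    stack = ow.render_stack(truth, render=ow.RenderSpec(noise=False))
    return truth, stack


def match_detections(det_xy, truth_xy, radius_um=3.0):
    """Greedy one-to-one matching by distance; returns (recall, precision)."""
    from scipy.spatial import cKDTree

    det_xy = np.asarray(det_xy, float)
    truth_xy = np.asarray(truth_xy, float)
    if len(det_xy) == 0:
        return 0.0, 0.0
    dd, ii = cKDTree(truth_xy).query(det_xy)
    used, tp = set(), 0
    for k in np.argsort(dd):
        if dd[k] <= radius_um and ii[k] not in used:
            used.add(ii[k])
            tp += 1
    return tp / len(truth_xy), tp / len(det_xy)
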