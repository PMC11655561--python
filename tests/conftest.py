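import numpy as np
import pytest

from engramap.topography import RoiContour


@pytest.fixture
def rect_roi() -> RoiContour:
    """Rectangle identical to its bounding box: 900 x 630 um."""
    return RoiContour(np.array([(0.0, 0.0), (900.0, 0.0), (900.0, 630.0), (0.0, 630.0)]))


@pytest.fixture
def quad_roi() -> RoiContour:
    """Non-rectangular quadrilateral with a slanted top edge.

    Chosen so that no 10x10 bin center lands exactly on an edge, keeping the
    comparison with the ray-casting oracle unambiguous.
    """
    return RoiContour(np.array([(0.0, 0.0), (100.0, 0.0), (100.0, 40.0), (0.0, 87.0)]))


def make_freezing_frame(groups, n_per_group, means, sd, rng, phases=("training-post", "reactivation", "test")):
    """Long-format freezing table with Normal noise, clamped to [0, 100].

    ``means[g][p]`` is the mean for group g, phase p.
    """
    import pandas as pd

    rows = []
    for g in groups:
        for a in range(n_per_group):
            animal = f"{g}-{a}"
            for p in phases:
                v = float(np.clip(rng.normal(means[g][p], sd), 0, 100))
                rows.append(
                    {"animal_id": animal, "group": g, "phase": p, "percent_freezing": v}
                )
    return pd.DataFrame(rows)
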