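import numpy as np
import pandas as pd
import pytest

from lymphoniche.io_formats import PanelTable


@pytest.fixture
def rng():
    return np.random.default_rng(20251001)


@pytest.fixture
def small_panel():
    """3 markers + 2 nuclear + 1 segmentation channel."""
    return PanelTable(
        pd.DataFrame(
            {
                "channel_name": ["CD19", "CD4", "Ki67", "DNA1", "DNA2", "SegKit"],
                "metal_tag": ["Nd142", "Gd156", "Er168", "Ir191", "Ir193", "Pt196"],
                "role": ["marker", "marker", "marker", "nuclear", "nuclear", "segmentation"],
                "excluded_from_clustering": [False, False, False, True, True, True],
            }
        )
    )


@pytest.fixture
def marker_panel():
    """All-marker panel for images without nuclear/segmentation channels."""

    def make(n):
        return PanelTable(
            pd.DataFrame(
                {
                    "channel_name": [f"ch{i}" for i in range(n)],
                    "metal_tag": [f"M{i}" for i in range(n)],
                    "role": ["marker"] * n,
                    "excluded_from_clustering": [False] * n,
                }
            )
        )

    return make


def make_cells(xy, clusters, roi_id="roi1", cell_ids=None):
    xy = np.asarray(xy, dtype=float)
    return pd.DataFrame(
        {
            "cell_id": cell_ids if cell_ids is not None else np.arange(1, len(xy) + 1),
            "roi_id": roi_id,
            "x_um": xy[:, 0],
            "y_um": xy[:, 1],
            "cluster": list(clusters),
        }
    )


@pytest.fixture
def cells_factory():
    return make_cells
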