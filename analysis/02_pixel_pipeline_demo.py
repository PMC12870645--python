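"""Exercise the pixel stages end-to-end on a rendered synthetic ROI.

Renders a small ROI (one follicle) into a multichannel image plus label mask,
plants one hot pixel, runs the four-rule pixel cleanup, quantifies cells, and
checks that per-cell argmax marker assignment recovers the planted
compartments.  Writes the cleanup report and the recovery rate to results/.
"""

import json
from pathlib import Path

import numpy as np

from lymphoniche.cell_quant import summarize_cells
from lymphoniche.pixel_preprocess import preprocess_rois
from lymphoniche.synthetic_data import (
    TissueSimParams,
    default_panel,
    generate_tissue,
    render_image,
)

SEED = 7
ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    params = TissueSimParams(
        roi_size_um=(400.0, 400.0), n_follicles=1, follicle_radius_um=60.0,
        mantle_width_um=25.0, marker_noise_sd=0.5, n_hot_pixels=1,
    )
    cells, _ = generate_tissue(params, seed=SEED)
    image, mask, render_truth = render_image(cells, params, seed=SEED)
    panel = default_panel()

    cleaned, report = preprocess_rois([image], panel)
    quant = summarize_cells(cleaned[0], mask)

    marker_cols = [c for c in quant.columns if c.startswith("M_")]
    called = quant[marker_cols].idxmax(axis=1).str.removeprefix("M_")
    truth_by_id = cells.set_index("cell_id")["compartment"]
    agreement = float((called.values == truth_by_id.loc[quant["cell_id"]].values).mean())

    # the planted hot pixel must be zeroed; at this noise level the 99.99th
    # percentile also catches a handful of noise-tail pixels, which is the
    # rule working as intended
    planted_zeroed = all(
        np.all(cleaned[0].data[:, r, c] == 0.0)
        for r, c in render_truth.hot_pixels["roi"]
    )
    out = {
        "n_cells_planted": int(len(cells)),
        "n_cells_quantified": int(len(quant)),
        "hot_pixels_planted": len(render_truth.hot_pixels.get("roi", [])),
        "hot_pixels_zeroed": report.hot_pixels_zeroed[image.roi_id],
        "planted_hot_pixel_zeroed": planted_zeroed,
        "compartment_call_agreement": agreement,
        "intensity_range": [float(cleaned[0].data.min()), float(cleaned[0].data.max())],
    }
    (ROOT / "results").mkdir(exist_ok=True)
    (ROOT / "results" / "pixel_pipeline_demo.json").write_text(json.dumps(out, indent=2))
    print(
        f"quantified {out['n_cells_quantified']}/{out['n_cells_planted']} cells; "
        f"hot pixels zeroed {out['hot_pixels_zeroed']} (planted "
        f"{out['hot_pixels_planted']}, zeroed: {planted_zeroed}); "
        f"argmax compartment agreement {agreement:.3f}"
    )
    assert planted_zeroed
    assert agreement > 0.95


if __name__ == "__main__":
    main()
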