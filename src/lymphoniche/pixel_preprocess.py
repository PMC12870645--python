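"""Four-rule pixel cleanup for imaging-mass-cytometry ROI stacks.

The rules run in a fixed order per ROI batch:

1. *Summed hot pixels* — per ROI, sum all channels per pixel; pixels whose sum
   strictly exceeds the within-ROI 99.99th percentile of the summed image are
   zeroed across every channel.
2. *Multi-channel artifacts* — per ROI, a pixel strictly exceeding the
   within-ROI 99.99th percentile in two or more of the specified protein
   channels is zeroed across every channel.
3. *Global median subtraction* — for each marker channel (excluding the
   nuclear DNA channels and the segmentation-kit channel), the median over
   all pixels of all ROIs is subtracted; negatives are clipped to zero.
4. *Percentile normalization* — per ROI and channel, intensities are divided
   by the within-ROI 99th percentile, clipped at 1, and scaled to 0-100.

Percentiles use linear interpolation between order statistics
(``numpy.percentile`` default); threshold exceedance is strict (">").
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_formats import ChannelImage, PanelTable

__all__ = [
    "PreprocessParams",
    "PreprocessReport",
    "zero_hot_pixels_summed",
    "zero_multichannel_artifacts",
    "subtract_global_medians",
    "percentile_normalize",
    "preprocess_rois",
]


@dataclass
class PreprocessParams:
    """Tunable knobs of the pixel cleanup.

    hot_pixel_percentile : percentile (0-100) above which a pixel counts as
        hot, applied within each ROI. Default 99.99.
    multi_channel_min_count : a pixel is an artifact when it is hot in at
        least this many of ``artifact_channel_set`` channels. Default 2.
    artifact_channel_set : channel names checked by rule 2; ``None`` means
        every channel in the image (the "specified protein channels" are not
        enumerated upstream, so the default is the most conservative set).
    normalize_percentile : per-channel percentile mapped to full scale.
    normalize_max : full-scale value (0-100 range by default).
    """

    hot_pixel_percentile: float = 99.99
    multi_channel_min_count: int = 2
    artifact_channel_set: list[str] | None = None
    normalize_percentile: float = 99.0
    normalize_max: float = 100.0
    median_scope: str = "global-across-images"

    def __post_init__(self) -> None:
        if not (0.0 < self.hot_pixel_percentile < 100.0):
            raise ValueError("hot_pixel_percentile must be in (0, 100)")
        if not (0.0 < self.normalize_percentile < 100.0):
            raise ValueError("normalize_percentile must be in (0, 100)")
        if self.multi_channel_min_count < 2:
            raise ValueError("multi_channel_min_count must be >= 2")
        if self.normalize_max <= 0:
            raise ValueError("normalize_max must be positive")
        if self.median_scope != "global-across-images":
            raise ValueError("only median_scope='global-across-images' is supported")


@dataclass
class PreprocessReport:
    """Per-ROI bookkeeping: pixels zeroed by each rule, medians, scale factors."""

    hot_pixels_zeroed: dict[str, int] = field(default_factory=dict)
    artifact_pixels_zeroed: dict[str, int] = field(default_factory=dict)
    channel_medians: dict[str, float] = field(default_factory=dict)
    normalize_p: dict[str, dict[str, float]] = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "hot_pixels_zeroed": self.hot_pixels_zeroed,
            "artifact_pixels_zeroed": self.artifact_pixels_zeroed,
            "channel_medians": self.channel_medians,
            "normalize_percentiles": self.normalize_p,
        }


def zero_hot_pixels_summed(
    image: ChannelImage, params: PreprocessParams | None = None
) -> tuple[ChannelImage, int]:
    """Zero pixels whose channel-summed intensity is above the hot percentile.

    Returns the cleaned image and the number of pixels zeroed.  On a constant
    image nothing strictly exceeds the percentile, so nothing is zeroed.
    """
    params = params or PreprocessParams()
    if image.n_channels < 1 or image.data.size == 0:
        raise ValueError("empty image")
    out = image.copy()
    summed = out.data.sum(axis=0)
    threshold = np.percentile(summed, params.hot_pixel_percentile)
    hot = summed > threshold
    out.data[:, hot] = 0.0
    return out, int(hot.sum())


def zero_multichannel_artifacts(
    image: ChannelImage, params: PreprocessParams | None = None
) -> tuple[ChannelImage, int]:
    """Zero pixels that are hot in >= ``multi_channel_min_count`` channels.

    Per-channel hot thresholds are the within-ROI ``hot_pixel_percentile`` of
    that channel; a flagged pixel is zeroed in *all* channels.
    """
    params = params or PreprocessParams()
    if image.data.size == 0:
        raise ValueError("empty image")
    channels = params.artifact_channel_set
    if channels is None:
        channels = list(image.channel_names)
    unknown = set(channels) - set(image.channel_names)
    if unknown:
        raise ValueError(f"artifact_channel_set names unknown channels: {sorted(unknown)}")
    out = image.copy()
    exceed = np.zeros(out.data.shape[1:], dtype=int)
    for name in channels:
        ch = out.channel(name)
        thr = np.percentile(ch, params.hot_pixel_percentile)
        exceed += ch > thr
    artifact = exceed >= params.multi_channel_min_count
    out.data[:, artifact] = 0.0
    return out, int(artifact.sum())


def subtract_global_medians(
    images: list[ChannelImage],
    panel: PanelTable,
    params: PreprocessParams | None = None,
) -> tuple[list[ChannelImage], dict[str, float]]:
    """Subtract the cross-ROI per-channel median background, clipping at zero.

    The median of each marker channel is taken over the pooled pixels of every
    ROI (nuclear and segmentation channels are left untouched), then
    subtracted from that channel in every ROI.
    """
    if not images:
        raise ValueError("need at least one image")
    marker_names = panel.background_subtracted_names
    if not marker_names:
        raise ValueError("panel has no marker channels to background-subtract")
    medians: dict[str, float] = {}
    for name in marker_names:
        pooled = np.concatenate([img.channel(name).ravel() for img in images])
        medians[name] = float(np.median(pooled))
    out = []
    for img in images:
        new = img.copy()
        for name in marker_names:
            idx = new.channel_names.index(name)
            new.data[idx] = np.clip(new.data[idx] - medians[name], 0.0, None)
        out.append(new)
    return out, medians


def percentile_normalize(
    image: ChannelImage, params: PreprocessParams | None = None
) -> tuple[ChannelImage, dict[str, float]]:
    """Map each channel to [0, normalize_max] by its within-ROI percentile.

    v -> min(v / p, 1) * normalize_max with p the channel's 99th percentile;
    an all-zero channel (p = 0) stays all-zero.
    """
    params = params or PreprocessParams()
    if image.data.size == 0:
        raise ValueError("empty image")
    out = image.copy()
    scales: dict[str, float] = {}
    for i, name in enumerate(out.channel_names):
        p = float(np.percentile(out.data[i], params.normalize_percentile))
        scales[name] = p
        if p <= 0:
            out.data[i] = 0.0
        else:
            out.data[i] = np.minimum(out.data[i] / p, 1.0) * params.normalize_max
    return out, scales


def preprocess_rois(
    images: list[ChannelImage],
    panel: PanelTable,
    params: PreprocessParams | None = None,
) -> tuple[list[ChannelImage], PreprocessReport]:
    """Apply the four cleanup rules in order and report per-rule counts."""
    params = params or PreprocessParams()
    report = PreprocessReport()
    stage1: list[ChannelImage] = []
    for img in images:
        cleaned, n_hot = zero_hot_pixels_summed(img, params)
        cleaned, n_art = zero_multichannel_artifacts(cleaned, params)
        report.hot_pixels_zeroed[img.roi_id] = n_hot
        report.artifact_pixels_zeroed[img.roi_id] = n_art
        stage1.append(cleaned)
    stage2, medians = subtract_global_medians(stage1, panel, params)
    report.channel_medians = medians
    out: list[ChannelImage] = []
    for img in stage2:
        normed, scales = percentile_normalize(img, params)
        report.normalize_p[img.roi_id] = scales
        out.append(normed)
    return out, report
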