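"""Two-channel colocalization statistics.

Reconstructs the standard readouts for immunofluorescence co-staining: the
Pearson correlation of voxel intensities over an analysis mask, and the
percentage of one channel's above-threshold voxels that are also
above-threshold in the other (Otsu thresholds per channel by default; an
intensity-weighted Manders-style variant is available).  3-D stacks are
analyzed voxel-wise over the whole stack.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.filters import threshold_otsu


class ZeroVarianceError(ValueError):
    """Correlation is undefined when a channel has no intensity variance."""


@dataclass
class ChannelPair:
    """Two intensity arrays of identical shape (2-D or 3-D) with an optional
    binary analysis mask restricting all statistics to the cell region."""

    channel_a: np.ndarray
    channel_b: np.ndarray
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.channel_a = np.asarray(self.channel_a)
        self.channel_b = np.asarray(self.channel_b)
        if self.channel_a.shape != self.channel_b.shape:
            raise ValueError("channels must have identical shapes")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, bool)
            if self.mask.shape != self.channel_a.shape:
                raise ValueError("mask shape must equal channel shape")

    def masked(self) -> tuple[np.ndarray, np.ndarray]:
        if self.mask is None:
            return self.channel_a.ravel().astype(float), self.channel_b.ravel().astype(float)
        return (
            self.channel_a[self.mask].astype(float),
            self.channel_b[self.mask].astype(float),
        )


@dataclass
class ColocResult:
    pearson_r: float
    pct_a_in_b: float
    pct_b_in_a: float
    threshold_a: float
    threshold_b: float
    threshold_method: str
    intensity_weighted: bool

    def to_dict(self) -> dict:
        return {
            "pearson_r": self.pearson_r,
            "pct_a_in_b": self.pct_a_in_b,
            "pct_b_in_a": self.pct_b_in_a,
            "threshold_a": self.threshold_a,
            "threshold_b": self.threshold_b,
            "threshold_method": self.threshold_method,
            "intensity_weighted": self.intensity_weighted,
        }


def pearson(pair: ChannelPair) -> float:
    """Sample Pearson correlation of the two channels over the mask."""
    a, b = pair.masked()
    if a.size < 2:
        raise ValueError("need at least 2 voxels")
    if a.std() == 0 or b.std() == 0:
        raise ZeroVarianceError("a channel has zero variance over the mask")
    return float(np.corrcoef(a, b)[0, 1])


def percent_overlap(
    pair: ChannelPair,
    threshold_method: str = "otsu",
    thresholds: tuple[float, float] | None = None,
    intensity_weighted: bool = False,
) -> tuple[float, float]:
    """Percent of each channel's signal colocalized with the other.

    Per-channel thresholds are computed with Otsu's method within the mask
    (or given explicitly via ``thresholds``).  By default the overlap is a
    voxel count: pct_a_in_b = 100 * |A+ and B+| / |A+|.  With
    ``intensity_weighted=True`` the Manders-style intensity fractions are
    returned instead (sums of channel-A intensity over the same voxel sets).
    """
    a, b = pair.masked()
    if thresholds is not None:
        ta, tb = thresholds
    elif threshold_method == "otsu":
        ta = float(threshold_otsu(a))
        tb = float(threshold_otsu(b))
    else:
        raise ValueError(f"unknown threshold method: {threshold_method}")
    above_a = a > ta
    above_b = b > tb
    if not above_a.any() or not above_b.any():
        raise ValueError("empty above-threshold set; overlap undefined")
    both = above_a & above_b
    if intensity_weighted:
        pct_ab = 100.0 * a[both].sum() / a[above_a].sum()
        pct_ba = 100.0 * b[both].sum() / b[above_b].sum()
    else:
        pct_ab = 100.0 * both.sum() / above_a.sum()
        pct_ba = 100.0 * both.sum() / above_b.sum()
    return float(pct_ab), float(pct_ba)


def coloc(
    pair: ChannelPair,
    threshold_method: str = "otsu",
    thresholds: tuple[float, float] | None = None,
    intensity_weighted: bool = False,
) -> ColocResult:
    """Full colocalization report: Pearson r plus percent-overlap both ways."""
    a, b = pair.masked()
    if thresholds is not None:
        ta, tb = thresholds
    else:
        ta, tb = float(threshold_otsu(a)), float(threshold_otsu(b))
    pct_ab, pct_ba = percent_overlap(
        pair, threshold_method, (ta, tb), intensity_weighted
    )
    return ColocResult(
        pearson_r=pearson(pair),
        pct_a_in_b=pct_ab,
        pct_b_in_a=pct_ba,
        threshold_a=ta,
        threshold_b=tb,
        threshold_method=threshold_method if thresholds is None else "manual",
        intensity_weighted=intensity_weighted,
    )
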