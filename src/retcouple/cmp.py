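"""Computational molecular phenotyping (CMP) of multichannel immunosignal images.

Small-molecule channels (GABA γ, glutamate E, glutamine Q, aspartate D,
glycine G, taurine τ, and the activity tracer AGB B) are acquired as 8-bit
registered serial sections. Pixel value maps log-linearly to intracellular
concentration, so a calibration model PV = pv_ref + slope · log10(c / c_ref)
converts between the two. Pixels are classified jointly across channels by
k-means into a *theme map*; masked per-class histograms, GABA-band
segmentation (γ− / provisionally coupled γ+ ganglion cell / amacrine),
colocalization RGB maps and connected-component soma counts complete the
pipeline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from skimage import measure
from sklearn.cluster import KMeans

CHANNEL_NAMES = ("γ", "E", "Q", "D", "G", "τ", "B")

# GABA concentration bands (mM): below the first bound there is no measurable
# GABA (γ− cells); the middle band marks provisionally coupled γ+ ganglion
# cells; the top band is the conventional amacrine-cell range. Values above
# the last bound are still amacrine-class.
GABA_THRESHOLDS_MM = (0.1, 1.0, 10.0)
GABA_CLASS_NAMES = ("gamma_negative", "gamma_positive_GC", "amacrine")


@dataclass
class ChannelStack:
    channels: dict[str, np.ndarray]
    registered: bool = True
    pixel_size_um: Optional[float] = None

    def __post_init__(self):
        shapes = {name: ch.shape for name, ch in self.channels.items()}
        if len(set(shapes.values())) > 1:
            raise ValueError(f"channel shapes differ: {shapes}")
        for name, ch in self.channels.items():
            if ch.dtype != np.uint8:
                raise ValueError(f"channel {name!r} must be 8-bit, got {ch.dtype}")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    def as_feature_matrix(self, order: Optional[Sequence[str]] = None) -> np.ndarray:
        """Pixels as rows, channels as columns (float), in the given order."""
        names = list(order) if order else sorted(self.channels)
        return np.stack([self.channels[n].ravel().astype(float) for n in names], axis=1)


@dataclass
class CalibrationModel:
    """Log-linear pixel-value <-> concentration map, clamped to [0, 255]."""

    pv_ref: float = 96.0
    c_ref_mM: float = 0.1
    slope_pv_per_decade: float = 64.0

    def __post_init__(self):
        if self.slope_pv_per_decade <= 0:
            raise ValueError("slope must be positive")

    def conc_to_pv(self, c_mM) -> np.ndarray | float:
        c = np.asarray(c_mM, dtype=float)
        if np.any(c <= 0):
            raise ValueError("concentration must be positive")
        pv = self.pv_ref + self.slope_pv_per_decade * np.log10(c / self.c_ref_mM)
        pv = np.clip(pv, 0.0, 255.0)
        return float(pv) if np.ndim(c_mM) == 0 else pv

    def pv_to_conc(self, pv) -> np.ndarray | float:
        p = np.asarray(pv, dtype=float)
        c = self.c_ref_mM * 10.0 ** ((p - self.pv_ref) / self.slope_pv_per_decade)
        return float(c) if np.ndim(pv) == 0 else c


def register_translation(
    img_a: np.ndarray, img_b: np.ndarray, max_shift_px: int = 10
) -> tuple[tuple[int, int], float]:
    """Integer (dx, dy) shift aligning img_b to img_a by cross-correlation.

    Exhaustively scores every shift within ±max_shift_px by the normalized
    zero-mean correlation of the overlap region; returns the best shift and
    its correlation score (low scores flag unreliable registrations).
    Shifting img_b by (dx, dy) — rows by dx, columns by dy — aligns it to a.
    """
    if img_a.shape != img_b.shape:
        raise ValueError(f"shape mismatch {img_a.shape} vs {img_b.shape}")
    if max_shift_px < 0:
        raise ValueError("max_shift_px must be >= 0")
    a = img_a.astype(float)
    b = img_b.astype(float)
    h, w = a.shape
    best = (0, 0)
    best_score = -np.inf
    for dx in range(-max_shift_px, max_shift_px + 1):
        for dy in range(-max_shift_px, max_shift_px + 1):
            a_sl = a[max(dx, 0): h + min(dx, 0), max(dy, 0): w + min(dy, 0)]
            b_sl = b[max(-dx, 0): h + min(-dx, 0), max(-dy, 0): w + min(-dy, 0)]
            if a_sl.size == 0:
                continue
            av = a_sl - a_sl.mean()
            bv = b_sl - b_sl.mean()
            denom = math.sqrt((av * av).sum() * (bv * bv).sum())
            score = (av * bv).sum() / denom if denom > 0 else 0.0
            if score > best_score or (score == best_score and (dx, dy) < best):
                best_score = score
                best = (dx, dy)
    return best, float(best_score)


@dataclass
class ThemeMap:
    labels: np.ndarray  # integer label image, 0..k-1
    signatures: np.ndarray  # (k, n_channels) mean signature per label
    channel_order: tuple[str, ...]
    k: int
    seed: int
    inertia: float


def cluster_theme_map(
    stack: ChannelStack, k: int, seed: int = 0, restarts: int = 10
) -> ThemeMap:
    """k-means classification of pixels by their joint channel signature.

    Best of `restarts` k-means++ initializations by within-cluster sum of
    squares; deterministic under a fixed seed. Output labels are relabelled
    in lexicographic order of the cluster mean signatures so that label
    identity does not depend on initialization order.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    order = tuple(sorted(stack.channels))
    X = stack.as_feature_matrix(order)
    n_distinct = len(np.unique(X, axis=0))
    if k > n_distinct:
        raise ValueError(f"k={k} exceeds {n_distinct} distinct pixel signatures")
    km = KMeans(n_clusters=k, init="k-means++", n_init=restarts, random_state=seed)
    raw = km.fit_predict(X)
    centers = km.cluster_centers_
    perm = np.lexsort(centers.T[::-1])  # sort by first channel, then second, ...
    remap = np.empty(k, dtype=int)
    remap[perm] = np.arange(k)
    labels = remap[raw].reshape(stack.shape)
    return ThemeMap(
        labels=labels,
        signatures=centers[perm],
        channel_order=order,
        k=k,
        seed=seed,
        inertia=float(km.inertia_),
    )


@dataclass
class SignatureHistogram:
    counts: np.ndarray  # 256 integer bins
    source_mask: str = ""

    def __post_init__(self):
        if self.counts.shape != (256,):
            raise ValueError("histogram must have 256 bins")

    @property
    def empty(self) -> bool:
        return int(self.counts.sum()) == 0

    @property
    def peak_normalized(self) -> np.ndarray:
        peak = self.counts.max()
        if peak == 0:
            return self.counts.astype(float)
        return self.counts / peak

    @property
    def unit_area(self) -> np.ndarray:
        total = self.counts.sum()
        if total == 0:
            return self.counts.astype(float)
        return self.counts / total

    def mode_pv(self) -> Optional[int]:
        if self.empty:
            return None
        return int(self.counts.argmax())


def masked_histogram(
    channel: np.ndarray, mask: np.ndarray, source_mask: str = ""
) -> SignatureHistogram:
    """256-bin pixel-value histogram of a channel under a boolean mask."""
    if channel.shape != mask.shape:
        raise ValueError("mask shape must match channel shape")
    values = channel[mask.astype(bool)]
    counts = np.bincount(values.ravel(), minlength=256)[:256]
    return SignatureHistogram(counts=counts, source_mask=source_mask)


def segment_gaba_classes(
    gaba_channel: np.ndarray,
    model: CalibrationModel,
    thresholds_mM: tuple[float, float, float] = GABA_THRESHOLDS_MM,
) -> np.ndarray:
    """Three-class GABA-band label map from a calibrated γ channel.

    Per pixel concentration c: class 0 (γ−) if c < t0; class 1 (provisional
    γ+ ganglion cell) if t0 <= c < t1; class 2 (amacrine) if c >= t1 —
    half-open bands, with concentrations above t2 still amacrine-class.
    """
    t0, t1, t2 = thresholds_mM
    if not (t0 < t1 < t2):
        raise ValueError(f"thresholds must increase, got {thresholds_mM}")
    conc = model.pv_to_conc(gaba_channel.astype(float))
    labels = np.zeros(gaba_channel.shape, dtype=np.uint8)
    labels[conc >= t0] = 1
    labels[conc >= t1] = 2
    return labels


_RGB_PLANES = {"r": (0,), "g": (1,), "b": (2,), "y": (0, 1)}


def colocalization_rgb(stack: ChannelStack, mapping: str) -> np.ndarray:
    """Build a 24-bit RGB colocalization image from a mapping like "γE::yb".

    Left of "::" are channel names, right are display letters r/g/b/y, one
    per channel; y duplicates the channel into both red and green. Multiple
    channels landing on one plane add, saturating at 255.
    """
    if "::" not in mapping:
        raise ValueError(f"mapping {mapping!r} must be '<channels>::<letters>'")
    chans, letters = mapping.split("::", 1)
    if len(chans) != len(letters):
        raise ValueError(f"mapping {mapping!r}: one display letter per channel required")
    out = np.zeros(stack.shape + (3,), dtype=np.uint16)
    for ch_name, letter in zip(chans, letters):
        if ch_name not in stack.channels:
            raise KeyError(f"channel {ch_name!r} not in stack")
        if letter not in _RGB_PLANES:
            raise ValueError(f"unknown display letter {letter!r} (use r, g, b or y)")
        for plane in _RGB_PLANES[letter]:
            out[..., plane] += stack.channels[ch_name]
    return np.clip(out, 0, 255).astype(np.uint8)


def count_objects(
    label_map: np.ndarray, target_label: int, min_area_px: int = 0
) -> pd.DataFrame:
    """8-connected components of one label, size-filtered to drop fragments.

    Small fragments (cross-sectioned dendrites rather than somas) are removed
    by min_area_px. Columns: object id, centroid row/col, area_px,
    equivalent_diameter_px.
    """
    binary = label_map == target_label
    cc = measure.label(binary, connectivity=2)
    rows = []
    for region in measure.regionprops(cc):
        if region.area < min_area_px:
            continue
        rows.append(
            {
                "object": region.label,
                "centroid_row": region.centroid[0],
                "centroid_col": region.centroid[1],
                "area_px": int(region.area),
                "equivalent_diameter_px": region.equivalent_diameter_area,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["object", "centroid_row", "centroid_col", "area_px", "equivalent_diameter_px"],
    )


def separability(hist_a: SignatureHistogram, hist_b: SignatureHistogram) -> dict:
    """Distributional separation of two signature histograms.

    Returns the two-sample KS statistic D (max CDF distance over the 256
    bins) and the overlap coefficient sum(min(pa, pb)) of the unit-area
    histograms. Identical histograms give D = 0, overlap = 1; disjoint
    supports give D = 1, overlap = 0.
    """
    if hist_a.empty or hist_b.empty:
        raise ValueError("histograms must be non-empty")
    pa, pb = hist_a.unit_area, hist_b.unit_area
    D = float(np.max(np.abs(np.cumsum(pa) - np.cumsum(pb))))
    overlap = float(np.minimum(pa, pb).sum())
    return {"ks_D": D, "overlap": overlap}
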