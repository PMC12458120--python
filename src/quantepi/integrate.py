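"""Two-mark integration: proximity linking, signal clustering, profiles.

Changed peaks of one mark (e.g. H3K27ac gains) are linked to the nearest
peak of a second mark (e.g. H3K27me1) within a +/- window, the linked
regions are stratified into low / intermediate / high tiers of
second-mark signal with k-means (k = 3 by default), and signal profiles
over queried coordinates are tabulated as matrices (reference-point or
scaled-region mode). A threshold filter for externally fitted
differential-expression tables rounds out the integration toolkit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .core import GenomicInterval, QuantTrack, ValidationError

__all__ = [
    "LinkedPair",
    "link_within",
    "ClusterAssignment",
    "cluster_by_signal",
    "ProfileMatrix",
    "profile_matrix",
    "filter_de",
]

TIER_NAMES = ["low", "intermediate", "high"]


@dataclass(frozen=True)
class LinkedPair:
    """An A-peak linked to its nearest B-peak within a distance window.

    ``distance`` is the signed edge-to-edge gap in bp: 0 when the
    intervals overlap, positive when the B-peak lies downstream (higher
    coordinates) of the A-peak, negative when upstream.
    """

    peak_a: GenomicInterval
    peak_b: GenomicInterval
    distance: int
    window: int


def _edge_distance(a: GenomicInterval, b: GenomicInterval) -> int | None:
    """Signed edge-to-edge distance; None when on different chromosomes."""
    if a.chrom != b.chrom:
        return None
    if a.start < b.end and b.start < a.end:
        return 0
    if b.start >= a.end:
        return b.start - a.end
    return -(a.start - b.end)


def link_within(
    peaks_a: list[GenomicInterval],
    peaks_b: list[GenomicInterval],
    window: int,
) -> list[LinkedPair]:
    """Link each A-peak to its nearest B-peak if within ``window`` bp.

    Distance is measured edge-to-edge (overlap = 0). Ties between two
    equidistant B-peaks go to the one with the smaller start. A-peaks with
    no B-peak inside the window are simply not emitted. Translation of all
    coordinates by a constant leaves pairs and distances unchanged.
    """
    if window <= 0:
        raise ValidationError("window must be > 0")
    b_by_chrom: dict[str, list[GenomicInterval]] = {}
    for b in sorted(peaks_b, key=lambda p: (p.chrom, p.start)):
        b_by_chrom.setdefault(b.chrom, []).append(b)
    pairs: list[LinkedPair] = []
    for a in peaks_a:
        candidates = b_by_chrom.get(a.chrom, [])
        best: tuple[int, int, GenomicInterval] | None = None  # |d|, start, peak
        for b in candidates:
            d = _edge_distance(a, b)
            key = (abs(d), b.start)
            if best is None or key < (best[0], best[1]):
                best = (abs(d), b.start, b)
        if best is not None and best[0] <= window:
            b = best[2]
            pairs.append(LinkedPair(a, b, _edge_distance(a, b), window))
    return pairs


@dataclass
class ClusterAssignment:
    """Tier labels for linked regions plus the ordered centroids.

    ``tiers`` aligns with the input pair list; ``centroids`` are in
    ascending order (low <= intermediate <= high). ``degenerate`` is set
    when all features are identical, in which case the tier labels are
    arbitrary.
    """

    tiers: list[str]
    centroids: list[float]
    features: np.ndarray
    degenerate: bool = False


def cluster_by_signal(
    pairs: list[LinkedPair],
    track_b: QuantTrack,
    window: int,
    k: int = 3,
    seed: int = 0,
) -> ClusterAssignment:
    """Stratify linked regions by second-mark signal with k-means.

    The feature for each pair is the mean track-B signal over
    ``[A-center - window, A-center + window)``. Initialisation is a
    deterministic farthest-point sweep over the features (the two
    extremes, then the point maximising the distance to the chosen
    centres), so the assignment is a pure function of the data; the seed
    only feeds the library RNG. Cluster labels are re-ordered so that
    ``low < intermediate < high`` by centroid.
    """
    if len(pairs) < k:
        raise ValidationError(f"need at least k={k} pairs, got {len(pairs)}")
    feats = np.array(
        [
            track_b.mean(p.peak_a.chrom, p.peak_a.center - window, p.peak_a.center + window)
            for p in pairs
        ]
    )
    if np.allclose(feats, feats[0]):
        return ClusterAssignment(
            tiers=[TIER_NAMES[0]] * len(pairs),
            centroids=[float(feats[0])] * k,
            features=feats,
            degenerate=True,
        )
    # farthest-point init: min, max, then greedily most-isolated points
    centers = [float(feats.min()), float(feats.max())]
    while len(centers) < k:
        dist = np.min(
            np.abs(feats[:, None] - np.array(centers)[None, :]), axis=1
        )
        centers.append(float(feats[int(np.argmax(dist))]))
    init = np.sort(np.array(centers)).reshape(-1, 1)
    km = KMeans(
        n_clusters=k,
        init=init,
        n_init=1,
        max_iter=50,
        random_state=int(seed) % (2**32),
    )
    labels = km.fit_predict(feats.reshape(-1, 1))
    centroids = km.cluster_centers_.ravel()
    order = np.argsort(centroids)
    rank = np.empty_like(order)
    rank[order] = np.arange(k)
    names = TIER_NAMES if k == 3 else [f"tier{i + 1}" for i in range(k)]
    tiers = [names[rank[lab]] for lab in labels]
    return ClusterAssignment(
        tiers=tiers,
        centroids=[float(centroids[i]) for i in order],
        features=feats,
    )


@dataclass
class ProfileMatrix:
    """Region x bin matrix of mean signal, plus the average profile.

    ``matrix`` has one row per region; NaN cells mark bins falling
    outside chromosome bounds. ``profile`` is the column mean over
    defined cells.
    """

    matrix: np.ndarray
    mode: str
    flank: int
    bin_size: int
    body_bins: int = 0

    @property
    def profile(self) -> np.ndarray:
        return np.nanmean(self.matrix, axis=0)

    @property
    def n_columns(self) -> int:
        return self.matrix.shape[1]


def profile_matrix(
    track: QuantTrack,
    regions: list[GenomicInterval],
    mode: str = "reference_point",
    flank: int = 1000,
    bin_size: int = 50,
    body_bins: int = 0,
) -> ProfileMatrix:
    """Tabulate mean signal in bins around (or across) each region.

    reference_point mode: ``2 * flank / bin_size`` bins of ``bin_size`` bp
    tiling ``[center - flank, center + flank)`` where the reference point
    is the region midpoint. scale_regions mode: ``flank / bin_size``
    upstream bins, ``body_bins`` bins each covering ``width / body_bins``
    of the region body (fractional bounds handled by exact integration of
    the step function), then the downstream flank. Cells are base-pair
    weighted means; bins extending past chromosome bounds (when the track
    knows them) are NaN and excluded from the average profile.
    """
    if mode not in ("reference_point", "scale_regions"):
        raise ValidationError(f"unknown mode {mode!r}")
    if flank % bin_size != 0:
        raise ValidationError("flank must be divisible by bin_size")
    if mode == "scale_regions" and body_bins < 1:
        raise ValidationError("scale_regions mode needs body_bins >= 1")
    n_flank = flank // bin_size
    n_cols = 2 * n_flank + (body_bins if mode == "scale_regions" else 0)
    lengths = track.chrom_lengths or {}
    mat = np.full((len(regions), n_cols), np.nan)
    for r, region in enumerate(regions):
        bounds: list[tuple[float, float]] = []
        if mode == "reference_point":
            left = region.center - flank
            bounds = [
                (left + i * bin_size, left + (i + 1) * bin_size)
                for i in range(n_cols)
            ]
        else:
            bounds = [
                (region.start - flank + i * bin_size, region.start - flank + (i + 1) * bin_size)
                for i in range(n_flank)
            ]
            step = region.width / body_bins
            bounds += [
                (region.start + i * step, region.start + (i + 1) * step)
                for i in range(body_bins)
            ]
            bounds += [
                (region.end + i * bin_size, region.end + (i + 1) * bin_size)
                for i in range(n_flank)
            ]
        chrom_len = lengths.get(region.chrom)
        for c, (lo, hi) in enumerate(bounds):
            if lo < 0 or (chrom_len is not None and hi > chrom_len):
                continue  # out of bounds -> stays NaN
            mat[r, c] = track.mean(region.chrom, lo, hi)
    return ProfileMatrix(
        matrix=mat,
        mode=mode,
        flank=flank,
        bin_size=bin_size,
        body_bins=body_bins if mode == "scale_regions" else 0,
    )


def filter_de(
    de_table: pd.DataFrame,
    lfc_min: float = 1.0,
    fdr_max: float = 0.01,
) -> tuple[set[str], set[str]]:
    """Split a differential-expression table into up / down gene sets.

    Inclusive bounds: up = {log2FC >= lfc_min and FDR <= fdr_max},
    down = {log2FC <= -lfc_min and FDR <= fdr_max}. Model fitting happens
    upstream; only the threshold filter is applied here.
    """
    lfc = de_table["log2FC"].to_numpy(dtype=float)
    fdr = de_table["FDR"].to_numpy(dtype=float)
    genes = de_table["gene"].astype(str)
    up = set(genes[(lfc >= lfc_min) & (fdr <= fdr_max)])
    down = set(genes[(lfc <= -lfc_min) & (fdr <= fdr_max)])
    return up, down
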