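"""Peak-level quantitative response between treatment and vehicle tracks.

A peak's *response* is the ratio of its track area (signal x bp) under
treatment to its area under vehicle, summarised as a log2 fold-change.
Each treatment replicate is compared to every vehicle replicate (the full
cross of pairings); a replicate's response is the mean of its pairings,
the peak's overall response is the mean over treatment replicates, and
the replicate-to-replicate variance of those means is kept for the
variance gate applied downstream.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .core import GenomicInterval, QuantTrack, ValidationError

__all__ = [
    "detect_peaks",
    "peak_area",
    "pair_log2fc",
    "replicate_response",
    "conserve_peaks",
]


def detect_peaks(
    track: QuantTrack,
    threshold: float,
    min_width: int = 1,
    merge_gap: int = 0,
) -> list[GenomicInterval]:
    """Segment a track into peaks by simple thresholding.

    Maximal runs of signal >= ``threshold`` are found per chromosome; runs
    whose gap is <= ``merge_gap`` bp are merged; merged runs narrower than
    ``min_width`` bp are dropped. Output is sorted and non-overlapping.
    """
    if threshold <= 0:
        raise ValidationError("threshold must be > 0")
    if min_width < 1:
        raise ValidationError("min_width must be >= 1")
    peaks: list[GenomicInterval] = []
    for chrom in sorted(track.chroms):
        starts, ends, values = track.arrays(chrom)
        runs: list[list[int]] = []
        for s, e, v in zip(starts, ends, values):
            if v < threshold:
                continue
            if runs and s - runs[-1][1] <= merge_gap:
                runs[-1][1] = max(runs[-1][1], int(e))
            else:
                runs.append([int(s), int(e)])
        peaks.extend(
            GenomicInterval(chrom, s, e) for s, e in runs if e - s >= min_width
        )
    return peaks


def peak_area(track: QuantTrack, peak: GenomicInterval) -> float:
    """Track area (signal x bp) inside one peak; uncovered bases count 0."""
    return track.area(peak.chrom, peak.start, peak.end)


def pair_log2fc(
    treat: QuantTrack,
    veh: QuantTrack,
    peak: GenomicInterval,
    pseudo: float = 1.0,
) -> float:
    """log2 area ratio for one treatment/vehicle track pairing.

    A symmetric pseudocount (signal*bp) on both areas guards zero coverage
    and preserves the arm-swap antisymmetry of the statistic.
    """
    if pseudo <= 0:
        raise ValidationError("pseudo must be > 0")
    a_t = peak_area(treat, peak) + pseudo
    a_v = peak_area(veh, peak) + pseudo
    return math.log2(a_t / a_v)


def replicate_response(
    treat_tracks: list[QuantTrack],
    veh_tracks: list[QuantTrack],
    peaks: list[GenomicInterval],
    pseudo: float = 1.0,
) -> pd.DataFrame:
    """Full-cross replicate response table over a set of peaks.

    Returns one row per peak with columns ``chrom, start, end, width``,
    one ``rep{i}_log2fc`` per treatment replicate (its mean over all
    vehicle pairings), ``mean_log2fc`` (mean of the replicate means),
    ``variance`` (unbiased sample variance of the replicate means; 0.0
    with a single treatment replicate) and ``n_replicates``.
    """
    if not treat_tracks or not veh_tracks:
        raise ValidationError("need at least one track per arm")
    n_rep = len(treat_tracks)
    rows = []
    for peak in peaks:
        rep_means = []
        for treat in treat_tracks:
            pair_fcs = [pair_log2fc(treat, veh, peak, pseudo) for veh in veh_tracks]
            rep_means.append(float(np.mean(pair_fcs)))
        mean_fc = float(np.mean(rep_means))
        variance = float(np.var(rep_means, ddof=1)) if n_rep > 1 else 0.0
        row = {
            "chrom": peak.chrom,
            "start": peak.start,
            "end": peak.end,
            "width": peak.width,
        }
        row.update({f"rep{i + 1}_log2fc": m for i, m in enumerate(rep_means)})
        row["mean_log2fc"] = mean_fc
        row["variance"] = variance
        row["n_replicates"] = n_rep
        rows.append(row)
    columns = ["chrom", "start", "end", "width"]
    columns += [f"rep{i + 1}_log2fc" for i in range(n_rep)]
    columns += ["mean_log2fc", "variance", "n_replicates"]
    return pd.DataFrame(rows, columns=columns)


def conserve_peaks(
    per_replicate_peaks: list[list[GenomicInterval]],
    min_replicates: int | None = None,
) -> list[GenomicInterval]:
    """Consensus peaks conserved across replicate peak sets.

    Peaks from all sets are grouped into connected components under
    any-base overlap; a component is conserved when it contains peaks from
    at least ``min_replicates`` distinct sets (default: all sets). The
    consensus interval is the union span of the component. The result is
    invariant to the order in which replicate sets are supplied.
    """
    n_sets = len(per_replicate_peaks)
    if min_replicates is None:
        min_replicates = n_sets
    if min_replicates > n_sets:
        raise ValidationError(
            f"min_replicates={min_replicates} exceeds number of sets ({n_sets})"
        )
    tagged = [
        (iv.chrom, iv.start, iv.end, set_idx)
        for set_idx, peak_set in enumerate(per_replicate_peaks)
        for iv in peak_set
    ]
    tagged.sort()
    consensus: list[GenomicInterval] = []
    comp: tuple[str, int, int, set[int]] | None = None  # chrom, start, max_end, sets

    def flush(c):
        if c is not None and len(c[3]) >= min_replicates:
            consensus.append(GenomicInterval(c[0], c[1], c[2]))

    for chrom, start, end, set_idx in tagged:
        if comp is not None and chrom == comp[0] and start < comp[2]:
            comp = (comp[0], comp[1], max(comp[2], end), comp[3] | {set_idx})
        else:
            flush(comp)
            comp = (chrom, start, end, {set_idx})
    flush(comp)
    return consensus
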