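"""Chromatin-state overlap enrichment and state condensation.

An 18-state chromHMM-style annotation (disjoint labeled intervals tiling
the genome) is compared against a peak set: for each state the fold
enrichment is the fraction of peak bases falling in the state divided by
the fraction of the genome the state occupies. *Enrichment bias* rescales
the folds of one peak set to percentages summing to 100, so state
profiles of differently sized peak sets are comparable.

Enrichment is base-pair weighted: a peak straddling two states
contributes its bases to each exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import GenomicInterval, ValidationError

__all__ = [
    "CONDENSATION_18_TO_4",
    "ChromStateAnnotation",
    "condense_states",
    "overlap_enrichment",
    "enrichment_bias",
]

# Standard collapse of the 18-state model into four broad categories.
CONDENSATION_18_TO_4: dict[str, str] = {
    "TssA": "Promoter",
    "TssFlnk": "Promoter",
    "TssFlnkD": "Promoter",
    "TssFlnkU": "Promoter",
    "TssBiv": "Promoter",
    "EnhBiv": "Enhancer",
    "EnhA1": "Enhancer",
    "EnhA2": "Enhancer",
    "EnhWk": "Enhancer",
    "EnhG1": "Enhancer",
    "EnhG2": "Enhancer",
    "TxWk": "Genic",
    "Tx": "Genic",
    "ReprPCWk": "Repressive",
    "ReprPC": "Repressive",
    "Het": "Repressive",
    "Quies": "Repressive",
    "ZNF/Rpts": "Repressive",
}


@dataclass
class ChromStateAnnotation:
    """Disjoint labeled intervals plus a genome length map.

    ``condensation`` maps fine state labels to broad categories; it is
    only consulted by :func:`condense_states`.
    """

    intervals: list[tuple[GenomicInterval, str]]
    chrom_lengths: dict[str, int]
    condensation: dict[str, str] = field(
        default_factory=lambda: dict(CONDENSATION_18_TO_4)
    )

    def __post_init__(self) -> None:
        self.intervals = sorted(
            self.intervals, key=lambda t: (t[0].chrom, t[0].start)
        )
        prev: GenomicInterval | None = None
        for iv, _ in self.intervals:
            if prev is not None and iv.chrom == prev.chrom and iv.start < prev.end:
                raise ValidationError(
                    f"overlapping annotation intervals at {iv.chrom}:{iv.start}"
                )
            prev = iv

    @property
    def labels(self) -> list[str]:
        return sorted({lab for _, lab in self.intervals})

    def genome_bp(self) -> int:
        return sum(self.chrom_lengths.values())

    def coverage_by_label(self) -> dict[str, int]:
        cov: dict[str, int] = {}
        for iv, lab in self.intervals:
            cov[lab] = cov.get(lab, 0) + iv.width
        return cov


def condense_states(annotation: ChromStateAnnotation) -> ChromStateAnnotation:
    """Replace state labels by their broad category and merge neighbours.

    Adjacent (touching) intervals sharing a category are merged; total
    coverage is conserved. An interval whose label is missing from the
    condensation map is an error naming the label.
    """
    merged: list[tuple[GenomicInterval, str]] = []
    for iv, lab in annotation.intervals:
        if lab not in annotation.condensation:
            raise ValidationError(f"state label {lab!r} missing from condensation map")
        cat = annotation.condensation[lab]
        if (
            merged
            and merged[-1][1] == cat
            and merged[-1][0].chrom == iv.chrom
            and merged[-1][0].end == iv.start
        ):
            prev_iv, _ = merged[-1]
            merged[-1] = (GenomicInterval(iv.chrom, prev_iv.start, iv.end), cat)
        else:
            merged.append((iv, cat))
    categories = sorted(set(annotation.condensation.values()))
    return ChromStateAnnotation(
        merged,
        dict(annotation.chrom_lengths),
        condensation={c: c for c in categories},
    )


def _overlap_bp(peaks: list[GenomicInterval], iv: GenomicInterval) -> int:
    total = 0
    for p in peaks:
        if p.chrom != iv.chrom:
            continue
        total += max(0, min(p.end, iv.end) - max(p.start, iv.start))
    return total


def overlap_enrichment(
    peaks: list[GenomicInterval], annotation: ChromStateAnnotation
) -> pd.DataFrame:
    """Per-state fold enrichment of a peak set over the annotation.

    ``fold(s) = (peak bp in s / total peak bp) / (state bp / genome bp)``.
    Returns a frame with columns ``state, overlap_bp, state_bp, fold``;
    a state with zero genomic coverage gets fold = NaN (undefined).
    """
    total_peak_bp = sum(p.width for p in peaks)
    if total_peak_bp == 0:
        raise ValidationError("peak set covers zero bases")
    genome_bp = annotation.genome_bp()
    # index peaks per chromosome, sorted, for interval sweep
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for p in sorted(peaks, key=lambda p: (p.chrom, p.start)):
        by_chrom.setdefault(p.chrom, []).append(p)

    overlap: dict[str, int] = {}
    state_bp: dict[str, int] = {}
    for iv, lab in annotation.intervals:
        state_bp[lab] = state_bp.get(lab, 0) + iv.width
        chrom_peaks = by_chrom.get(iv.chrom, [])
        starts = np.array([p.start for p in chrom_peaks])
        ends = np.array([p.end for p in chrom_peaks])
        if len(starts):
            lo = int(np.searchsorted(ends, iv.start, side="right"))
            hi = int(np.searchsorted(starts, iv.end, side="left"))
            if hi > lo:
                ov = np.minimum(ends[lo:hi], iv.end) - np.maximum(
                    starts[lo:hi], iv.start
                )
                overlap[lab] = overlap.get(lab, 0) + int(ov.clip(0).sum())
    rows = []
    for lab in sorted(state_bp):
        s_bp = state_bp[lab]
        ov = overlap.get(lab, 0)
        fold = (
            (ov / total_peak_bp) / (s_bp / genome_bp) if s_bp > 0 else float("nan")
        )
        rows.append(
            {"state": lab, "overlap_bp": ov, "state_bp": s_bp, "fold": fold}
        )
    return pd.DataFrame(rows, columns=["state", "overlap_bp", "state_bp", "fold"])


def enrichment_bias(result: pd.DataFrame) -> pd.DataFrame:
    """Add a ``bias_pct`` column: each fold as % of the summed folds.

    States with undefined (NaN) fold are excluded from the denominator
    and receive NaN bias; the defined biases sum to 100.
    """
    out = result.copy()
    folds = out["fold"].to_numpy(dtype=float)
    defined = ~np.isnan(folds)
    if not defined.any():
        raise ValidationError("no defined fold enrichments")
    total = folds[defined].sum()
    if total == 0:
        raise ValidationError("all fold enrichments are zero")
    bias = np.full(len(out), np.nan)
    bias[defined] = 100.0 * folds[defined] / total
    out["bias_pct"] = bias
    return out
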