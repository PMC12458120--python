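"""Per-CpG group differences and contiguous-probe DMR calling.

The region criterion: a run of at least ``min_cpgs`` consecutive array
probes (adjacent probes no more than ``max_gap`` bp apart), all shifted
in the same direction, whose mean beta difference between groups reaches
``min_delta`` in absolute value, is a differentially methylated region.
Runs are reported maximal — not extendable without breaking the sign or
gap constraint. Array probes are sparse, so an unbounded gap would merge
unrelated loci; the default gap bound is 1,000 bp.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import BetaMatrix, GenomicInterval, ValidationError

__all__ = ["DMR", "delta_beta", "call_dmrs"]


@dataclass(frozen=True)
class DMR:
    """A called differentially methylated region.

    Spans the first to last member probe (half-open on the last probe's
    base); ``direction`` is hyper when the second group is more
    methylated, hypo when less.
    """

    interval: GenomicInterval
    n_probes: int
    mean_delta: float
    direction: str
    probe_indices: tuple[int, ...]


def delta_beta(
    matrix: BetaMatrix, group_a: list[str], group_b: list[str]
) -> pd.DataFrame:
    """Per-probe difference of group mean betas (group_b minus group_a).

    Conventionally group_a is the vehicle arm and group_b the treated
    arm, so positive deltas mean methylation gained under treatment.
    Returns a frame with probe_id / chrom / pos / delta, position-sorted.
    """
    for col in group_a + group_b:
        if col not in matrix.beta.columns:
            raise ValidationError(f"unknown sample column {col!r}")
    delta = matrix.group_mean(group_b) - matrix.group_mean(group_a)
    out = matrix.probes[["probe_id", "chrom", "pos"]].copy()
    out["delta"] = delta
    return out


def call_dmrs(
    deltas: pd.DataFrame,
    min_cpgs: int = 5,
    min_delta: float = 0.20,
    max_gap: int = 1000,
    per_probe: bool = False,
) -> list[DMR]:
    """Scan position-sorted per-probe deltas for maximal qualifying runs.

    A run is a maximal stretch of consecutive probes with the same
    non-zero delta sign whose neighbours are <= ``max_gap`` bp apart. The
    run is a DMR when it has >= ``min_cpgs`` probes and its mean |delta|
    is >= ``min_delta``. With ``per_probe=True`` the stricter reading is
    used instead: every member probe's own |delta| must reach
    ``min_delta`` (sign runs are first trimmed to sub-runs of qualifying
    probes). Adjacent runs separated by a sign flip are never merged.
    """
    required = {"probe_id", "chrom", "pos", "delta"}
    if not required.issubset(deltas.columns):
        raise ValidationError(f"delta table needs columns {sorted(required)}")
    dmrs: list[DMR] = []
    for chrom, sub in deltas.groupby("chrom", sort=True):
        pos = sub["pos"].to_numpy(dtype=np.int64)
        if np.any(np.diff(pos) <= 0):
            raise ValidationError(f"{chrom}: probes not strictly position-sorted")
        d = sub["delta"].to_numpy(dtype=float)
        idx = sub.index.to_numpy()
        runs = _sign_runs(pos, d, max_gap)
        for run in runs:
            if per_probe:
                for piece in _split_by_magnitude(run, d, min_delta):
                    dmr = _admit(chrom, pos, d, idx, piece, min_cpgs, min_delta)
                    if dmr is not None:
                        dmrs.append(dmr)
            else:
                dmr = _admit(chrom, pos, d, idx, run, min_cpgs, min_delta)
                if dmr is not None:
                    dmrs.append(dmr)
    return dmrs


def _sign_runs(pos: np.ndarray, d: np.ndarray, max_gap: int) -> list[list[int]]:
    """Maximal runs of same-sign non-zero deltas within the gap bound."""
    runs: list[list[int]] = []
    current: list[int] = []
    for i in range(len(d)):
        if d[i] == 0 or np.isnan(d[i]):
            if current:
                runs.append(current)
            current = []
            continue
        if (
            current
            and np.sign(d[i]) == np.sign(d[current[-1]])
            and pos[i] - pos[current[-1]] <= max_gap
        ):
            current.append(i)
        else:
            if current:
                runs.append(current)
            current = [i]
    if current:
        runs.append(current)
    return runs


def _split_by_magnitude(
    run: list[int], d: np.ndarray, min_delta: float
) -> list[list[int]]:
    """Trim a sign run to maximal sub-runs of per-probe |delta| >= min_delta."""
    pieces: list[list[int]] = []
    current: list[int] = []
    for i in run:
        if abs(d[i]) >= min_delta:
            current.append(i)
        else:
            if current:
                pieces.append(current)
            current = []
    if current:
        pieces.append(current)
    return pieces


def _admit(
    chrom: str,
    pos: np.ndarray,
    d: np.ndarray,
    idx: np.ndarray,
    run: list[int],
    min_cpgs: int,
    min_delta: float,
) -> DMR | None:
    if len(run) < min_cpgs:
        return None
    mean_delta = float(np.mean(d[run]))
    if abs(mean_delta) < min_delta:
        return None
    first, last = run[0], run[-1]
    return DMR(
        interval=GenomicInterval(chrom, int(pos[first]), int(pos[last]) + 1),
        n_probes=len(run),
        mean_delta=mean_delta,
        direction="hyper" if mean_delta > 0 else "hypo",
        probe_indices=tuple(int(idx[i]) for i in run),
    )


def dmrs_to_bed(dmrs: list[DMR], path) -> None:
    """Export DMRs as BED4+score: name = direction, score = 1000*|mean delta|."""
    with open(path, "w") as fh:
        for dmr in dmrs:
            score = min(1000, int(round(1000 * abs(dmr.mean_delta))))
            fh.write(
                f"{dmr.interval.chrom}\t{dmr.interval.start}\t{dmr.interval.end}"
                f"\t{dmr.direction}\t{score}\n"
            )
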