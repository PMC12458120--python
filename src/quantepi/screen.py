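"""Arrayed-screen normalisation, exclusion filters and Z-score hit calling.

Each well holds one siRNA pool targeting one gene; raw luminescence
(RLU) reports reporter reactivation and imaged confluency (%) proxies
cell number. The score is background-subtracted RLU per % confluency.
Two exclusion filters guard against false positives: genes with CPM
below a floor in every provided expression condition (reactivation of a
silent reporter cannot be read through a gene that is not expressed),
and wells whose confluency falls more than a set number of SDs below the
screen mean (toxicity confounds the luminescence readout). Hits are
wells whose score Z (over retained wells) strictly exceeds the cutoff.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import ValidationError

__all__ = ["normalize_wells", "filter_wells", "call_hits"]


def normalize_wells(wells: pd.DataFrame, background: float = 0.0) -> pd.DataFrame:
    """Add a ``score`` column: max(RLU - background, 0) / confluency.

    Wells with confluency <= 0 are flagged invalid and carry no score.
    """
    if background < 0:
        raise ValidationError("background must be >= 0")
    out = wells.copy()
    rlu = out["RLU"].to_numpy(dtype=float)
    conf = out["confluency"].to_numpy(dtype=float)
    invalid = conf <= 0
    score = np.full(len(out), np.nan)
    score[~invalid] = np.maximum(rlu[~invalid] - background, 0.0) / conf[~invalid]
    out["score"] = score
    out["invalid"] = invalid
    return out


def filter_wells(
    wells: pd.DataFrame,
    cpm_table: pd.DataFrame,
    cpm_min: float = 100.0,
    sd_mult: float = 1.0,
) -> pd.DataFrame:
    """Flag low-expression and toxic wells.

    ``low_expression``: the gene's CPM is below ``cpm_min`` in *all*
    provided expression conditions (a gene expressed in any condition is
    kept); genes absent from the CPM table count as CPM 0. ``toxic``:
    confluency below mean - sd_mult * SD, with mean and unbiased SD taken
    over all valid wells.
    """
    out = wells.copy()
    cpm_cols = [c for c in cpm_table.columns if c != "gene"]
    if not cpm_cols:
        raise ValidationError("CPM table has no condition columns")
    max_cpm = cpm_table.set_index("gene")[cpm_cols].max(axis=1)
    gene_cpm = out["gene"].map(max_cpm).fillna(0.0).to_numpy(dtype=float)
    out["low_expression"] = gene_cpm < cpm_min

    valid = ~out["invalid"] if "invalid" in out.columns else np.ones(len(out), bool)
    conf = out.loc[valid, "confluency"].to_numpy(dtype=float)
    mean, sd = float(conf.mean()), float(conf.std(ddof=1))
    out["toxic"] = out["confluency"].to_numpy(dtype=float) < mean - sd_mult * sd
    return out


def call_hits(wells: pd.DataFrame, z_min: float = 4.0) -> pd.DataFrame:
    """Z-score retained wells and call hits at Z strictly above ``z_min``.

    Retained = not invalid, not low_expression, not toxic. Z uses the
    mean and unbiased SD of retained scores; flagged wells carry no Z and
    can never be hits. Returns the table with ``zscore`` and ``hit``
    columns, hits ranked first by descending Z.
    """
    out = wells.copy()
    flags = np.zeros(len(out), dtype=bool)
    for col in ("invalid", "low_expression", "toxic"):
        if col in out.columns:
            flags |= out[col].to_numpy(dtype=bool)
    retained = ~flags
    if retained.sum() < 2:
        raise ValidationError("need at least 2 retained wells")
    scores = out.loc[retained, "score"].to_numpy(dtype=float)
    mean, sd = float(scores.mean()), float(scores.std(ddof=1))
    if sd == 0:
        raise ValidationError("retained scores have zero standard deviation")
    z = np.full(len(out), np.nan)
    z[retained] = (out.loc[retained, "score"].to_numpy(dtype=float) - mean) / sd
    out["zscore"] = z
    out["hit"] = retained & (z > z_min)
    return out.sort_values(
        ["hit", "zscore"], ascending=[False, False], kind="mergesort"
    ).reset_index(drop=True)
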