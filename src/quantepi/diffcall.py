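"""Differential calls from a response table, and narrow/broad shape classes.

Calling is a fixed-threshold rule, not a hypothesis test: a peak is a
*gain* when its mean log2 fold-change is at or above the mark's gain
threshold, a *loss* at or below the loss threshold, otherwise not
significant. Marks whose replicate responses are noisy (H3K27me1-style
configs) additionally carry a variance ceiling: a peak whose
replicate-to-replicate variance exceeds the ceiling is never called.
All comparisons are inclusive.

Shape classification fits a two-component Gaussian mixture to log10 peak
widths — quantitative ChIP peak-width distributions show a dense mode of
short (~300-400 bp) peaks plus a tail of broader domains — and labels a
peak *narrow* when the posterior of the smaller-mean component is >= 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.mixture import GaussianMixture

from .core import ValidationError

__all__ = [
    "MarkConfig",
    "H3K27AC",
    "H3K27ME1",
    "call_differential",
    "WidthMixture",
    "fit_width_mixture",
    "classify_shapes",
    "DegenerateInputError",
]


class DegenerateInputError(ValueError):
    """Too few or identical widths: fit 2 components is meaningless; treat
    the population as a single shape class instead."""


@dataclass(frozen=True)
class MarkConfig:
    """Per-mark significance thresholds on the mean log2 fold-change."""

    mark: str
    gain_threshold: float
    loss_threshold: float
    variance_ceiling: float | None = None

    def __post_init__(self) -> None:
        if not (self.gain_threshold > 0 > self.loss_threshold):
            raise ValidationError("need gain threshold > 0 > loss threshold")
        if self.variance_ceiling is not None and self.variance_ceiling <= 0:
            raise ValidationError("variance ceiling must be > 0")


# log2(1.5) = 0.585: a 1.5-fold gain criterion, paired with a 2-fold loss
# criterion, for the acetylation mark; the monomethyl mark uses symmetric
# +/-0.5 thresholds plus a replicate-variance ceiling of 1.
H3K27AC = MarkConfig("H3K27ac", gain_threshold=0.585, loss_threshold=-1.0)
H3K27ME1 = MarkConfig(
    "H3K27me1", gain_threshold=0.5, loss_threshold=-0.5, variance_ceiling=1.0
)


def call_differential(responses: pd.DataFrame, config: MarkConfig) -> pd.DataFrame:
    """Append a ``call`` column (gain / loss / not_significant).

    Deterministic inclusive thresholding on ``mean_log2fc``; when the
    config carries a variance ceiling, a ``variance`` above it forces
    not_significant regardless of effect size.
    """
    out = responses.copy()
    mean = out["mean_log2fc"].to_numpy(dtype=float)
    call = np.full(len(out), "not_significant", dtype=object)
    call[mean >= config.gain_threshold] = "gain"
    call[mean <= config.loss_threshold] = "loss"
    if config.variance_ceiling is not None:
        var = out["variance"].to_numpy(dtype=float)
        call[var > config.variance_ceiling] = "not_significant"
    out["call"] = call
    return out


@dataclass(frozen=True)
class WidthMixture:
    """Two-component Gaussian mixture on log10 peak width.

    Component 0 is always the smaller-mean ("narrow") component.
    """

    means: tuple[float, float]
    sds: tuple[float, float]
    weights: tuple[float, float]

    def posterior_narrow(self, widths_bp) -> np.ndarray:
        """Posterior probability of the narrow component per width."""
        x = np.log10(np.asarray(widths_bp, dtype=float))
        mu = np.array(self.means)
        sd = np.array(self.sds)
        w = np.array(self.weights)
        log_dens = (
            np.log(w)
            - np.log(sd)
            - 0.5 * np.log(2 * np.pi)
            - 0.5 * ((x[:, None] - mu) / sd) ** 2
        )
        log_dens -= log_dens.max(axis=1, keepdims=True)
        dens = np.exp(log_dens)
        return dens[:, 0] / dens.sum(axis=1)


def _two_means_split(x_sorted: np.ndarray) -> int:
    """Exact 1-D 2-means: index i minimising within-class SS of x[:i] | x[i:]."""
    n = len(x_sorted)
    csum = np.concatenate([[0.0], np.cumsum(x_sorted)])
    csq = np.concatenate([[0.0], np.cumsum(x_sorted**2)])
    best_i, best_ss = 1, np.inf
    for i in range(1, n):
        ss_left = csq[i] - csum[i] ** 2 / i
        ss_right = (csq[n] - csq[i]) - (csum[n] - csum[i]) ** 2 / (n - i)
        ss = ss_left + ss_right
        if ss < best_ss:
            best_ss, best_i = ss, i
    return best_i


def fit_width_mixture(
    widths_bp, seed: int = 0
) -> tuple[WidthMixture, np.ndarray]:
    """EM-fit the narrow/broad width mixture; returns (mixture, posterior).

    Widths are modelled on the log10 scale (strictly positive and
    right-skewed on the raw scale). EM is initialised from the exact
    two-means split of the sorted log-widths, which makes the fit a pure
    function of the data; ``seed`` only feeds the library RNG and does not
    change the result. Posterior is P(narrow) per input width.

    Raises :class:`DegenerateInputError` for fewer than 10 widths or a
    width list without at least 2 distinct values — callers should fall
    back to a single shape class.
    """
    widths = np.asarray(widths_bp, dtype=float)
    if len(widths) < 10:
        raise DegenerateInputError(
            f"need >= 10 widths to fit a 2-component mixture, got {len(widths)}; "
            "treat all peaks as one shape class"
        )
    if np.any(widths <= 0):
        raise ValidationError("widths must be positive")
    x = np.log10(widths)
    if np.unique(x).size < 2:
        raise DegenerateInputError(
            "all widths identical; treat all peaks as one shape class"
        )
    xs = np.sort(x)
    split = _two_means_split(xs)
    left, right = xs[:split], xs[split:]
    means_init = np.array([[left.mean()], [right.mean()]])
    weights_init = np.array([split, len(xs) - split], dtype=float) / len(xs)
    var_init = np.array(
        [max(left.var(), 1e-6), max(right.var(), 1e-6)]
    ).reshape(2, 1, 1)
    gm = GaussianMixture(
        n_components=2,
        covariance_type="full",
        means_init=means_init,
        weights_init=weights_init,
        precisions_init=1.0 / var_init,
        max_iter=300,
        reg_covar=1e-9,
        random_state=int(seed) % (2**32),
    )
    gm.fit(x.reshape(-1, 1))
    mu = gm.means_.ravel()
    sd = np.sqrt(gm.covariances_.ravel())
    w = gm.weights_.ravel()
    order = np.argsort(mu)  # component 0 = narrow
    mixture = WidthMixture(
        means=tuple(float(mu[i]) for i in order),
        sds=tuple(float(sd[i]) for i in order),
        weights=tuple(float(w[i]) for i in order),
    )
    return mixture, mixture.posterior_narrow(widths)


def classify_shapes(calls: pd.DataFrame, mixture: WidthMixture) -> pd.DataFrame:
    """Append ``posterior_narrow`` and ``shape`` (narrow/broad) columns.

    A peak is narrow when its posterior for the smaller-mean component is
    >= 0.5 (ties go to narrow).
    """
    out = calls.copy()
    post = mixture.posterior_narrow(out["width"].to_numpy(dtype=float))
    out["posterior_narrow"] = post
    out["shape"] = np.where(post >= 0.5, "narrow", "broad")
    return out
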