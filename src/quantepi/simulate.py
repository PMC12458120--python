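"""Synthetic genomes, tracks, beta matrices and screen plates with truth.

Every generator is a pure function of (config, seed): it emulates one
measured object of the study design — multi-replicate quantitative ChIP
tracks with multiplicative treatment effects on peak areas, an 18-state
chromatin annotation, methylation beta values with planted contiguous
DMR runs, and a genome-wide arrayed reporter screen with planted
activating hits and toxic genes — and returns a machine-readable truth
table alongside the data, so every downstream caller can be scored
against known ground truth.

Peaks are rectangular (constant height over their width), which makes
area ratios analytically exact: with replicate noise CV = 0, a planted
fold-change of 2.0 yields a treatment/vehicle area ratio of exactly 2.0.
Replicate noise is multiplicative lognormal on peak height (unit mean),
preserving non-negativity. Peak widths are drawn on the log10 scale from
a two-component mixture: a dense narrow mode (~350 bp) and a broad tail
(~2,000 bp).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .chromstate import CONDENSATION_18_TO_4, ChromStateAnnotation
from .core import BetaMatrix, GenomicInterval, QuantTrack, ValidationError

__all__ = [
    "SimulationConfig",
    "simulate_annotation",
    "simulate_tracks",
    "simulate_beta",
    "simulate_screen",
]

# Rough genome composition for the default 18-state annotation: mostly
# quiescent, with small promoter/enhancer fractions — enough structure to
# exercise enrichment without pretending to be a real segmentation.
DEFAULT_STATE_PROPORTIONS: dict[str, float] = {
    "TssA": 0.010,
    "TssFlnk": 0.005,
    "TssFlnkD": 0.005,
    "TssFlnkU": 0.005,
    "TssBiv": 0.005,
    "EnhBiv": 0.005,
    "EnhA1": 0.010,
    "EnhA2": 0.010,
    "EnhWk": 0.020,
    "EnhG1": 0.005,
    "EnhG2": 0.005,
    "TxWk": 0.100,
    "Tx": 0.050,
    "ReprPCWk": 0.050,
    "ReprPC": 0.020,
    "Het": 0.020,
    "Quies": 0.670,
    "ZNF/Rpts": 0.005,
}

# Fixed per-generator stream tags: each generator seeds its own RNG from
# (master seed, tag) so stages are independent yet reproducible.
_STREAMS = {"annotation": 1, "tracks": 2, "beta": 3, "screen": 4}


@dataclass
class SimulationConfig:
    """Study-design parameters for all four generators."""

    seed: int = 0
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"chr1": 2_000_000}
    )

    # annotation
    state_proportions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_STATE_PROPORTIONS)
    )
    condensation: dict[str, str] = field(
        default_factory=lambda: dict(CONDENSATION_18_TO_4)
    )
    annotation_bin: int = 200

    # quantitative tracks: 2 treatment-style replicates vs 2 vehicle,
    # multiplicative 10% CV replicate noise, 2x gains / 0.4x losses
    n_peaks: int = 200
    frac_gain: float = 0.2
    frac_loss: float = 0.2
    gain_fc: float = 2.0
    loss_fc: float = 0.4
    narrow_mean_bp: float = 350.0
    narrow_log10_sd: float = 0.08
    broad_mean_bp: float = 2000.0
    broad_log10_sd: float = 0.12
    narrow_weight: float = 0.6
    n_replicates_treat: int = 2
    n_replicates_veh: int = 2
    noise_cv: float = 0.10
    baseline_height: float = 1.0
    background_level: float = 0.05
    min_peak_separation: int = 2000

    # methylation: 3 samples per arm, mid-range background betas, small
    # technical noise; planted runs as (start_index, n_probes, delta)
    n_cpgs: int = 2000
    n_samples_per_group: int = 3
    beta_alpha: float = 2.0
    beta_beta: float = 2.0
    beta_noise_sd: float = 0.02
    probe_spacing: tuple[int, int] = (50, 500)
    dmr_specs: list[tuple[int, int, float]] = field(
        default_factory=lambda: [(100, 8, 0.30), (300, 4, 0.50), (500, 6, 0.15), (700, 10, -0.30)]
    )

    # screen: ~18,000-gene whole-genome library; healthy wells reach
    # confluency tightly around 80% while toxic knockdowns collapse to
    # 10-40%, so the long left tail they create dominates the
    # confluency SD that the one-SD viability filter is computed from
    n_genes: int = 18000
    n_hits: int = 50
    hit_effect_sd: float = 8.0
    n_toxic: int = 100
    n_low_expression: int = 500
    confluency_mean: float = 80.0
    confluency_sd: float = 2.0
    toxic_confluency_range: tuple[float, float] = (10.0, 40.0)
    score_mean: float = 20.0
    score_sd: float = 2.0
    rlu_background: float = 50.0

    def __post_init__(self) -> None:
        if self.noise_cv < 0:
            raise ValidationError("noise_cv must be >= 0")
        for name in ("n_peaks", "n_cpgs", "n_genes", "n_hits", "n_toxic"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if self.gain_fc <= 0 or self.loss_fc <= 0:
            raise ValidationError("fold-changes must be > 0")
        if self.hit_effect_sd <= 0:
            raise ValidationError("hit effect must be > 0")
        specs = sorted(self.dmr_specs)
        for (s1, n1, d1), (s2, _, _) in zip(specs, specs[1:]):
            if s1 + n1 > s2:
                raise ValidationError("planted DMR probe runs overlap")
        for _, n, d in self.dmr_specs:
            if not -1.0 <= d <= 1.0:
                raise ValidationError("planted delta must lie in [-1, 1]")
            if n < 1:
                raise ValidationError("planted run needs >= 1 probe")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["dmr_specs"] = [list(t) for t in self.dmr_specs]
        d["probe_spacing"] = list(self.probe_spacing)
        d["toxic_confluency_range"] = list(self.toxic_confluency_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "dmr_specs" in d:
            d["dmr_specs"] = [tuple(t) for t in d["dmr_specs"]]
        if "probe_spacing" in d:
            d["probe_spacing"] = tuple(d["probe_spacing"])
        if "toxic_confluency_range" in d:
            d["toxic_confluency_range"] = tuple(d["toxic_confluency_range"])
        return cls(**d)


def _rng(config: SimulationConfig, stream: str) -> np.random.Generator:
    return np.random.default_rng([_STREAMS[stream], int(config.seed) % 2**31])


def simulate_annotation(config: SimulationConfig) -> ChromStateAnnotation:
    """Tile each chromosome with states drawn at the configured proportions.

    Chromosomes are tiled with ``annotation_bin``-bp bins; each bin's
    state is drawn independently at the configured proportions and
    adjacent same-state bins are merged, so the tiling is exact and
    per-state coverages sum to the chromosome length. States with
    proportion 0 never appear.
    """
    props = config.state_proportions
    total = sum(props.values())
    if abs(total - 1.0) > 1e-9:
        raise ValidationError(f"state proportions sum to {total}, expected 1")
    rng = _rng(config, "annotation")
    labels = sorted(props)
    p = np.array([props[s] for s in labels])
    intervals: list[tuple[GenomicInterval, str]] = []
    for chrom in sorted(config.chrom_lengths):
        length = config.chrom_lengths[chrom]
        edges = list(range(0, length, config.annotation_bin)) + [length]
        n_bins = len(edges) - 1
        choice = rng.choice(len(labels), size=n_bins, p=p)
        start_idx = 0
        for i in range(1, n_bins + 1):
            if i == n_bins or choice[i] != choice[start_idx]:
                intervals.append(
                    (
                        GenomicInterval(chrom, edges[start_idx], edges[i]),
                        labels[choice[start_idx]],
                    )
                )
                start_idx = i
    return ChromStateAnnotation(
        intervals, dict(config.chrom_lengths), condensation=dict(config.condensation)
    )


def _lognormal_factor(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Unit-mean multiplicative noise with the given coefficient of variation."""
    if cv == 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv**2))
    return np.exp(rng.normal(-(sigma**2) / 2, sigma, size=size))


def simulate_tracks(
    config: SimulationConfig,
    annotation: ChromStateAnnotation | None = None,
) -> tuple[dict[str, list[QuantTrack]], list[GenomicInterval], pd.DataFrame]:
    """Plant peaks with treatment effects into replicate tracks per arm.

    Returns ``(tracks, peaks, truth)`` where ``tracks`` maps arm name
    ("treat"/"veh") to its replicate :class:`QuantTrack` list, ``peaks``
    are the planted intervals, and ``truth`` records each peak's class
    (gain/loss/null), fold-change and width component. Vehicle peak
    heights are baseline x lognormal noise; treatment heights are
    additionally multiplied by the planted fold-change. Peaks placed with
    a minimum separation; placement failure after bounded retries is an
    error. The annotation argument is accepted for interface symmetry
    (placement is annotation-agnostic).
    """
    del annotation
    if config.n_replicates_treat < 1 or config.n_replicates_veh < 1:
        raise ValidationError("need >= 1 replicate per arm")
    rng = _rng(config, "tracks")
    chroms = sorted(config.chrom_lengths)
    chrom_p = np.array([config.chrom_lengths[c] for c in chroms], dtype=float)
    chrom_p /= chrom_p.sum()

    n = config.n_peaks
    is_narrow = rng.random(n) < config.narrow_weight
    log_mean = np.where(
        is_narrow, np.log10(config.narrow_mean_bp), np.log10(config.broad_mean_bp)
    )
    log_sd = np.where(is_narrow, config.narrow_log10_sd, config.broad_log10_sd)
    widths = np.maximum(
        10, np.round(10 ** rng.normal(log_mean, log_sd)).astype(int)
    )

    placed: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    peak_rows = []
    for i in range(n):
        w = int(widths[i])
        for _attempt in range(1000):
            chrom = chroms[int(rng.choice(len(chroms), p=chrom_p))]
            length = config.chrom_lengths[chrom]
            margin = config.min_peak_separation
            if length - w - 2 * margin <= 0:
                continue
            start = int(rng.integers(margin, length - w - margin))
            end = start + w
            sep = config.min_peak_separation
            if all(
                end + sep <= s or e + sep <= start for s, e in placed[chrom]
            ):
                placed[chrom].append((start, end))
                peak_rows.append((chrom, start, end))
                break
        else:
            raise ValidationError(
                f"could not place peak {i} without overlap after 1000 retries"
            )

    n_gain = int(round(config.frac_gain * n))
    n_loss = int(round(config.frac_loss * n))
    if n_gain + n_loss > n:
        raise ValidationError("frac_gain + frac_loss exceeds 1")
    classes = np.array(
        ["gain"] * n_gain + ["loss"] * n_loss + ["null"] * (n - n_gain - n_loss)
    )
    rng.shuffle(classes)
    fc = np.where(
        classes == "gain",
        config.gain_fc,
        np.where(classes == "loss", config.loss_fc, 1.0),
    )
    heights = config.baseline_height * rng.uniform(0.5, 1.5, size=n)

    arms = {"treat": config.n_replicates_treat, "veh": config.n_replicates_veh}
    tracks: dict[str, list[QuantTrack]] = {}
    for arm, n_rep in arms.items():
        arm_fc = fc if arm == "treat" else np.ones(n)
        tracks[arm] = []
        for _rep in range(n_rep):
            noise = _lognormal_factor(rng, config.noise_cv, n)
            peak_height = heights * arm_fc * noise
            records: list[tuple[str, int, int, float]] = []
            for chrom in chroms:
                length = config.chrom_lengths[chrom]
                chrom_peaks = sorted(
                    (s, e, peak_height[j])
                    for j, (c, s, e) in enumerate(peak_rows)
                    if c == chrom
                )
                cursor = 0
                for s, e, h in chrom_peaks:
                    if s > cursor and config.background_level > 0:
                        records.append((chrom, cursor, s, config.background_level))
                    records.append((chrom, s, e, float(h)))
                    cursor = e
                if cursor < length and config.background_level > 0:
                    records.append((chrom, cursor, length, config.background_level))
            tracks[arm].append(
                QuantTrack.from_records(records, chrom_lengths=dict(config.chrom_lengths))
            )

    peaks = [GenomicInterval(c, s, e) for c, s, e in peak_rows]
    truth = pd.DataFrame(
        {
            "peak_id": [f"peak_{i:05d}" for i in range(n)],
            "chrom": [c for c, _, _ in peak_rows],
            "start": [s for _, s, _ in peak_rows],
            "end": [e for _, _, e in peak_rows],
            "width": widths,
            "class": classes,
            "fold_change": fc,
            "width_component": np.where(is_narrow, "narrow", "broad"),
            "height": heights,
        }
    )
    return tracks, peaks, truth


def simulate_beta(
    config: SimulationConfig,
) -> tuple[BetaMatrix, pd.DataFrame]:
    """Two-group beta matrix with planted contiguous-probe DMR runs.

    Background per-probe methylation is Beta-distributed; every sample
    value is the probe mean plus Gaussian technical noise, clipped to
    [0, 1]. Within each planted run the treated group's probe means are
    shifted by the planted delta before noise and clipping. The truth
    table lists each planted run's probe index range, genomic span and
    delta.
    """
    rng = _rng(config, "beta")
    n = config.n_cpgs
    for start, run_len, _ in config.dmr_specs:
        if start + run_len > n:
            raise ValidationError("planted run extends past the probe array")
    lo, hi = config.probe_spacing
    spacings = rng.integers(lo, hi + 1, size=n)
    pos = 1000 + np.cumsum(spacings)
    chrom = "chr1"
    m = rng.beta(config.beta_alpha, config.beta_beta, size=n)

    shift = np.zeros(n)
    truth_rows = []
    for run_id, (start, run_len, delta) in enumerate(sorted(config.dmr_specs)):
        shift[start : start + run_len] = delta
        truth_rows.append(
            {
                "run_id": f"dmr_{run_id}",
                "start_index": start,
                "n_probes": run_len,
                "delta": delta,
                "chrom": chrom,
                "start_pos": int(pos[start]),
                "end_pos": int(pos[start + run_len - 1]) + 1,
            }
        )

    k = config.n_samples_per_group
    veh_cols = [f"veh_{i + 1}" for i in range(k)]
    trt_cols = [f"trt_{i + 1}" for i in range(k)]
    data = {}
    for col in veh_cols:
        data[col] = np.clip(
            m + rng.normal(0, config.beta_noise_sd, size=n) if config.beta_noise_sd > 0 else m,
            0.0,
            1.0,
        )
    for col in trt_cols:
        noisy = m + shift
        if config.beta_noise_sd > 0:
            noisy = noisy + rng.normal(0, config.beta_noise_sd, size=n)
        data[col] = np.clip(noisy, 0.0, 1.0)

    probes = pd.DataFrame(
        {
            "probe_id": [f"cg{i:06d}" for i in range(n)],
            "chrom": chrom,
            "pos": pos,
        }
    )
    matrix = BetaMatrix(
        probes=probes,
        beta=pd.DataFrame(data, columns=veh_cols + trt_cols),
        sample_groups={"vehicle": veh_cols, "treated": trt_cols},
    )
    return matrix, pd.DataFrame(truth_rows)


def simulate_screen(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Arrayed reporter-screen plate with planted hits and toxic genes.

    Null wells draw confluency and normalised score from the configured
    Gaussians; hit wells shift the score by ``hit_effect_sd`` null SDs;
    toxic wells collapse to the configured low confluency range, far
    below the one-SD exclusion boundary; low-expression genes get CPM
    below the conventional floor in both expression conditions. Raw RLU
    is reconstructed from score and confluency so the consumer must redo
    the normalisation.
    """
    n_planted = config.n_hits + config.n_toxic + config.n_low_expression
    if config.n_genes < n_planted:
        raise ValidationError("screen smaller than planted gene sets")
    rng = _rng(config, "screen")
    n = config.n_genes
    genes = np.array([f"GENE{i:05d}" for i in range(n)])
    planted = rng.choice(n, size=n_planted, replace=False)
    hit_idx = planted[: config.n_hits]
    toxic_idx = planted[config.n_hits : config.n_hits + config.n_toxic]
    low_idx = planted[config.n_hits + config.n_toxic :]

    conf = np.clip(
        rng.normal(config.confluency_mean, config.confluency_sd, size=n), 1.0, 100.0
    )
    t_lo, t_hi = config.toxic_confluency_range
    conf[toxic_idx] = rng.uniform(t_lo, t_hi, size=len(toxic_idx))
    score = rng.normal(config.score_mean, config.score_sd, size=n)
    score[hit_idx] += config.hit_effect_sd * config.score_sd
    rlu = np.maximum(score, 0.0) * conf + config.rlu_background

    wells = pd.DataFrame(
        {
            "well": [f"W{i:05d}" for i in range(n)],
            "gene": genes,
            "RLU": rlu,
            "confluency": conf,
        }
    )

    cpm_basal = rng.uniform(100.0, 1000.0, size=n)
    cpm_dac = rng.uniform(100.0, 1000.0, size=n)
    cpm_basal[low_idx] = rng.uniform(0.0, 99.0, size=len(low_idx))
    cpm_dac[low_idx] = rng.uniform(0.0, 99.0, size=len(low_idx))
    cpm = pd.DataFrame({"gene": genes, "cpm_basal": cpm_basal, "cpm_dac": cpm_dac})

    cls = np.array(["null"] * n, dtype=object)
    cls[hit_idx] = "hit"
    cls[toxic_idx] = "toxic"
    cls[low_idx] = "low_expression"
    effect = np.zeros(n)
    effect[hit_idx] = config.hit_effect_sd
    truth = pd.DataFrame({"gene": genes, "class": cls, "effect_sd": effect})
    return wells, cpm, truth
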