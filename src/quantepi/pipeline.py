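"""End-to-end synthetic demo pipeline with a reproducibility manifest.

Runs simulate -> respond -> call -> enrich -> integrate -> dmr -> screen
on fully synthetic inputs, writing every intermediate to the output
directory together with a JSON manifest of seeds, per-stage summary
counts and SHA-256 hashes of every file. Re-running with the same config
and seed reproduces every output byte-identically (no timestamps are
recorded).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .chromstate import condense_states, enrichment_bias, overlap_enrichment
from .core import GenomicInterval, ValidationError
from .diffcall import H3K27AC, call_differential, classify_shapes, fit_width_mixture
from .io import write_bed, write_bedgraph
from .integrate import cluster_by_signal, link_within, profile_matrix
from .methylation import call_dmrs, delta_beta, dmrs_to_bed
from .response import conserve_peaks, detect_peaks, replicate_response
from .screen import call_hits, filter_wells, normalize_wells
from .simulate import (
    SimulationConfig,
    simulate_annotation,
    simulate_beta,
    simulate_screen,
    simulate_tracks,
)

__all__ = ["run_demo"]


class StageError(RuntimeError):
    """A pipeline stage failed; message names the stage and the cause."""


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def run_demo(
    config: SimulationConfig,
    outdir: str | Path,
    peak_threshold: float = 0.2,
    link_window: int = 10_000,
) -> dict:
    """Run the full synthetic pipeline; returns the manifest dict.

    ``peak_threshold`` segments peaks from each treatment replicate track
    (well above the simulated background, well below peak heights);
    ``link_window`` is the +/- proximity window for two-mark linking.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    counts: dict[str, dict] = {}
    stage = "simulate"
    try:
        annotation = simulate_annotation(config)
        tracks, peaks, peak_truth = simulate_tracks(config, annotation)
        beta, beta_truth = simulate_beta(config)
        wells, cpm, screen_truth = simulate_screen(config)

        (out / "config.yaml").write_text(
            yaml.safe_dump(config.to_dict(), sort_keys=True)
        )
        for arm, arm_tracks in tracks.items():
            for i, track in enumerate(arm_tracks):
                write_bedgraph(track, out / f"{arm}_rep{i + 1}.bedGraph")
        write_bed(peaks, out / "planted_peaks.bed")
        write_bed(
            [iv for iv, _ in annotation.intervals],
            out / "chromhmm.bed",
            names=[lab for _, lab in annotation.intervals],
        )
        _write_tsv(peak_truth, out / "truth_peaks.tsv")
        _write_tsv(beta_truth, out / "truth_dmrs.tsv")
        _write_tsv(screen_truth, out / "truth_screen.tsv")
        beta_table = pd.concat([beta.probes, beta.beta], axis=1)
        _write_tsv(beta_table, out / "beta.tsv")
        _write_tsv(wells, out / "screen_wells.tsv")
        _write_tsv(cpm, out / "screen_cpm.tsv")
        counts["simulate"] = {
            "n_peaks": len(peaks),
            "n_cpgs": len(beta.probes),
            "n_wells": len(wells),
            "n_states": len(annotation.labels),
        }

        stage = "respond"
        rep_peaks = [
            detect_peaks(t, threshold=peak_threshold, min_width=50)
            for t in tracks["treat"]
        ]
        consensus = conserve_peaks(rep_peaks)
        responses = replicate_response(
            tracks["treat"], tracks["veh"], consensus, pseudo=1.0
        )
        _write_tsv(responses, out / "response.tsv")
        counts["respond"] = {"n_consensus_peaks": len(consensus)}

        stage = "call"
        calls = call_differential(responses, H3K27AC)
        mixture, _ = fit_width_mixture(
            responses["width"].to_numpy(), seed=config.seed
        )
        calls = classify_shapes(calls, mixture)
        _write_tsv(calls, out / "calls.tsv")
        gains = [
            GenomicInterval(r.chrom, r.start, r.end)
            for r in calls.itertuples()
            if r.call == "gain"
        ]
        losses = [
            GenomicInterval(r.chrom, r.start, r.end)
            for r in calls.itertuples()
            if r.call == "loss"
        ]
        write_bed(gains, out / "gains.bed")
        write_bed(losses, out / "losses.bed")
        counts["call"] = {
            "n_gain": len(gains),
            "n_loss": len(losses),
            "n_not_significant": int((calls["call"] == "not_significant").sum()),
            "n_narrow": int((calls["shape"] == "narrow").sum()),
            "n_broad": int((calls["shape"] == "broad").sum()),
        }
        if not gains:
            raise ValidationError("no gains called; cannot continue demo")

        stage = "enrich"
        condensed = condense_states(annotation)
        enr = enrichment_bias(overlap_enrichment(gains, condensed))
        _write_tsv(enr, out / "enrichment_gains.tsv")
        counts["enrich"] = {"n_categories": len(enr)}

        stage = "integrate"
        pairs = link_within(gains, consensus, window=link_window)
        clusters = (
            cluster_by_signal(
                pairs, tracks["veh"][0], window=link_window, k=3, seed=config.seed
            )
            if len(pairs) >= 3
            else None
        )
        pair_df = pd.DataFrame(
            {
                "a_chrom": [p.peak_a.chrom for p in pairs],
                "a_start": [p.peak_a.start for p in pairs],
                "a_end": [p.peak_a.end for p in pairs],
                "b_start": [p.peak_b.start for p in pairs],
                "b_end": [p.peak_b.end for p in pairs],
                "distance": [p.distance for p in pairs],
                "tier": clusters.tiers if clusters else ["unclustered"] * len(pairs),
            }
        )
        _write_tsv(pair_df, out / "linked_pairs.tsv")
        prof = profile_matrix(
            tracks["treat"][0], gains, mode="reference_point", flank=1000, bin_size=50
        )
        prof_df = pd.DataFrame(
            prof.matrix,
            columns=[
                f"bin_{-prof.flank + i * prof.bin_size}"
                for i in range(prof.n_columns)
            ],
        )
        _write_tsv(prof_df, out / "profile_gains.tsv")
        counts["integrate"] = {
            "n_linked": len(pairs),
            "n_profile_columns": prof.n_columns,
        }

        stage = "dmr"
        deltas = delta_beta(
            beta, beta.sample_groups["vehicle"], beta.sample_groups["treated"]
        )
        dmrs = call_dmrs(deltas)
        dmr_df = pd.DataFrame(
            {
                "chrom": [d.interval.chrom for d in dmrs],
                "start": [d.interval.start for d in dmrs],
                "end": [d.interval.end for d in dmrs],
                "n_probes": [d.n_probes for d in dmrs],
                "mean_delta": [d.mean_delta for d in dmrs],
                "direction": [d.direction for d in dmrs],
            }
        )
        _write_tsv(dmr_df, out / "dmrs.tsv")
        dmrs_to_bed(dmrs, out / "dmrs.bed")
        counts["dmr"] = {
            "n_dmrs": len(dmrs),
            "n_hyper": sum(d.direction == "hyper" for d in dmrs),
            "n_hypo": sum(d.direction == "hypo" for d in dmrs),
        }

        stage = "screen"
        scored = call_hits(
            filter_wells(normalize_wells(wells, background=config.rlu_background), cpm)
        )
        _write_tsv(scored, out / "screen_scored.tsv")
        counts["screen"] = {
            "n_hits": int(scored["hit"].sum()),
            "n_toxic_flagged": int(scored["toxic"].sum()),
            "n_low_expression": int(scored["low_expression"].sum()),
        }
    except Exception as exc:
        raise StageError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest = {
        "package": "quantepi",
        "version": __version__,
        "seed": config.seed,
        "stages": counts,
        "files": {
            p.name: _sha256(p)
            for p in sorted(out.iterdir())
            if p.is_file() and p.name != "manifest.json"
        },
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    return manifest
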