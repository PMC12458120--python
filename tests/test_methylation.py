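"""Delta-beta computation and the contiguous-CpG DMR criterion."""

import numpy as np
import pandas as pd
import pytest

from quantepi.core import BetaMatrix, ValidationError
from quantepi.methylation import call_dmrs, delta_beta
from quantepi.simulate import SimulationConfig, simulate_beta


def beta_matrix(values_by_sample, positions=None):
    n = len(next(iter(values_by_sample.values())))
    positions = positions or list(range(100, 100 + 100 * n, 100))
    probes = pd.DataFrame(
        {
            "probe_id": [f"cg{i}" for i in range(n)],
            "chrom": ["chr1"] * n,
            "pos": positions,
        }
    )
    return BetaMatrix(probes=probes, beta=pd.DataFrame(values_by_sample))


def delta_frame(deltas, positions=None, chrom="chr1"):
    n = len(deltas)
    positions = positions or list(range(100, 100 + 100 * n, 100))
    return pd.DataFrame(
        {
            "probe_id": [f"cg{i}" for i in range(n)],
            "chrom": [chrom] * n,
            "pos": positions,
            "delta": deltas,
        }
    )


class TestDeltaBeta:
    def test_identical_groups_zero(self):
        m = beta_matrix({"a1": [0.2, 0.8], "b1": [0.2, 0.8]})
        assert delta_beta(m, ["a1"], ["b1"])["delta"].tolist() == [0.0, 0.0]

    def test_treated_minus_vehicle_sign(self):
        m = beta_matrix({"v1": [0.8], "v2": [0.8], "t1": [0.5], "t2": [0.5]})
        d = delta_beta(m, ["v1", "v2"], ["t1", "t2"])
        assert d["delta"].iloc[0] == pytest.approx(-0.3)

    def test_single_sample_groups(self):
        m = beta_matrix({"a": [0.1], "b": [0.35]})
        assert delta_beta(m, ["a"], ["b"])["delta"].iloc[0] == pytest.approx(0.25)

    def test_unknown_sample_errors(self):
        m = beta_matrix({"a": [0.1]})
        with pytest.raises(ValidationError, match="zzz"):
            delta_beta(m, ["a"], ["zzz"])


class TestCallDmrs:
    def test_eight_probe_run_called(self):
        deltas = [0.0] * 5 + [0.30] * 8 + [0.0] * 5
        [dmr] = call_dmrs(delta_frame(deltas))
        assert dmr.n_probes == 8
        assert dmr.mean_delta == pytest.approx(0.30)
        assert dmr.direction == "hyper"
        # interval spans first to last member probe
        assert dmr.interval.start == 100 + 5 * 100
        assert dmr.interval.end == 100 + 12 * 100 + 1

    def test_four_probes_too_few(self):
        deltas = [0.0] * 3 + [0.50] * 4 + [0.0] * 3
        assert call_dmrs(delta_frame(deltas)) == []

    def test_mean_below_threshold_rejected(self):
        deltas = [0.0] * 3 + [0.15] * 6 + [0.0] * 3
        assert call_dmrs(delta_frame(deltas)) == []

    def test_sign_flip_splits_runs(self):
        deltas = [0.30] * 5 + [-0.30] * 5
        dmrs = call_dmrs(delta_frame(deltas))
        assert [d.direction for d in dmrs] == ["hyper", "hypo"]
        assert all(d.n_probes == 5 for d in dmrs)

    def test_large_gap_splits_runs(self):
        positions = [100, 200, 300, 400, 500, 5000, 5100, 5200, 5300, 5400]
        deltas = [0.30] * 10
        dmrs = call_dmrs(delta_frame(deltas, positions), max_gap=1000)
        assert len(dmrs) == 2
        assert [d.n_probes for d in dmrs] == [5, 5]

    def test_per_probe_mode_is_stricter(self):
        # run mean 0.24 passes the region-mean rule but two probes
        # are individually below 0.20
        deltas = [0.0] * 2 + [0.30, 0.30, 0.10, 0.30, 0.30, 0.10, 0.34] + [0.0] * 2
        assert len(call_dmrs(delta_frame(deltas))) == 1
        assert call_dmrs(delta_frame(deltas), per_probe=True) == []

    def test_unsorted_probes_error(self):
        frame = delta_frame([0.3] * 6, positions=[100, 50, 200, 300, 400, 500])
        with pytest.raises(ValidationError, match="sorted"):
            call_dmrs(frame)

    def test_output_always_satisfies_criterion(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            deltas = rng.choice(
                [0.0, 0.05, -0.05, 0.25, -0.25, 0.4], size=80
            ) * rng.random(80)
            positions = np.cumsum(rng.integers(50, 1500, size=80)).tolist()
            for dmr in call_dmrs(delta_frame(deltas.tolist(), positions)):
                assert dmr.n_probes >= 5
                assert abs(dmr.mean_delta) >= 0.20
                member = deltas[[p for p in dmr.probe_indices]]
                assert np.all(np.sign(member) == np.sign(dmr.mean_delta))


def brute_force_dmrs(positions, deltas, min_cpgs=5, min_delta=0.20, max_gap=1000):
    """Quadratic enumeration oracle: every index run is tested directly.

    A run [i, j] is admissible when all member deltas share a non-zero
    sign and neighbour gaps are within bound; it is maximal when it can
    be extended in neither direction without breaking sign or gap. The
    reported set is the maximal admissible runs passing the size and
    region-mean thresholds.
    """
    pos = np.asarray(positions)
    d = np.asarray(deltas, dtype=float)
    n = len(d)

    def admissible(i, j):
        window = d[i : j + 1]
        if np.any(window == 0) or np.any(np.isnan(window)):
            return False
        if len(set(np.sign(window))) != 1:
            return False
        return np.all(np.diff(pos[i : j + 1]) <= max_gap)

    out = []
    for i in range(n):
        for j in range(i, n):
            if not admissible(i, j):
                continue
            ext_left = i > 0 and admissible(i - 1, j)
            ext_right = j < n - 1 and admissible(i, j + 1)
            if ext_left or ext_right:
                continue  # not maximal
            if j - i + 1 >= min_cpgs and abs(d[i : j + 1].mean()) >= min_delta:
                out.append((i, j))
    return out


class TestBruteForceOracle:
    def test_matches_scan_on_random_chromosomes(self):
        rng = np.random.default_rng(1)
        for _ in range(30):
            n = int(rng.integers(5, 200))
            deltas = np.round(
                rng.choice([0.0, 1.0, -1.0], size=n, p=[0.3, 0.35, 0.35])
                * rng.uniform(0.02, 0.5, size=n),
                3,
            )
            positions = np.cumsum(rng.integers(50, 1500, size=n))
            scanned = call_dmrs(delta_frame(deltas.tolist(), positions.tolist()))
            expected = brute_force_dmrs(positions, deltas)
            got = [
                (dmr.probe_indices[0], dmr.probe_indices[-1]) for dmr in scanned
            ]
            assert got == expected


class TestPlantedRecovery:
    def test_zero_noise_exact_boundaries(self):
        # with no technical noise, background deltas are exactly zero and
        # every qualifying planted run is recovered probe-for-probe
        config = SimulationConfig(seed=3, beta_noise_sd=0.0)
        matrix, truth = simulate_beta(config)
        deltas = delta_beta(
            matrix,
            matrix.sample_groups["vehicle"],
            matrix.sample_groups["treated"],
        )
        dmrs = call_dmrs(deltas)
        qualifying = truth[(truth["n_probes"] >= 5) & (truth["delta"].abs() >= 0.20)]
        assert len(dmrs) == len(qualifying)
        found = {(d.interval.start, d.interval.end, d.n_probes) for d in dmrs}
        for row in qualifying.itertuples():
            assert (row.start_pos, row.end_pos, row.n_probes) in found

    def test_noisy_background_keeps_oracle_equivalence(self):
        # under technical noise the scan still equals the brute-force
        # oracle (the planted run may legitimately absorb same-sign
        # boundary probes)
        config = SimulationConfig(
            seed=4,
            beta_noise_sd=0.02,
            n_cpgs=150,
            dmr_specs=[(20, 8, 0.30), (60, 10, -0.30)],
        )
        matrix, _ = simulate_beta(config)
        deltas = delta_beta(
            matrix,
            matrix.sample_groups["vehicle"],
            matrix.sample_groups["treated"],
        )
        scanned = call_dmrs(deltas)
        expected = brute_force_dmrs(
            deltas["pos"].to_numpy(), deltas["delta"].to_numpy()
        )
        assert [
            (d.probe_indices[0], d.probe_indices[-1]) for d in scanned
        ] == expected
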