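"""Pink-noise synthesis, the Euler-Maruyama update, determinism and event
labeling."""

import numpy as np
import pytest
from scipy import stats

from dynamotypes.integrate import (
    IntegratorConfig,
    generate_pink_noise,
    integrate,
    label_events,
)
from dynamotypes.registry import get_recipe


class TestPinkNoise:
    def test_deterministic_per_seed(self):
        a = generate_pink_noise(4096, seed=7).samples
        b = generate_pink_noise(4096, seed=7).samples
        assert np.array_equal(a, b)
        c = generate_pink_noise(4096, seed=8).samples
        assert not np.array_equal(a, c)

    def test_unit_variance_at_large_n(self):
        x = generate_pink_noise(2**16, seed=1).samples
        assert x.std() == pytest.approx(1.0, abs=0.05)
        assert abs(x.mean()) < 3 / np.sqrt(len(x))

    def test_spectral_slope_near_minus_one_over_two_decades(self):
        x = generate_pink_noise(2**16, seed=3).samples
        freqs = np.fft.rfftfreq(len(x))
        p = np.abs(np.fft.rfft(x)) ** 2
        mask = (freqs >= 1e-3) & (freqs <= 1e-1)  # two decades
        # average the periodogram in log-spaced bins before regressing
        edges = np.logspace(-3, -1, 25)
        fl, pl = [], []
        for lo, hi in zip(edges[:-1], edges[1:]):
            m = mask & (freqs >= lo) & (freqs < hi)
            if m.sum():
                fl.append(np.sqrt(lo * hi))
                pl.append(p[m].mean())
        lr = stats.linregress(np.log10(fl), np.log10(pl))
        assert lr.slope == pytest.approx(-1.0, abs=0.2)

    def test_rejects_empty(self):
        with pytest.raises(ValueError):
            generate_pink_noise(0, seed=0)


@pytest.fixture(scope="module")
def sn_sh_path(curves):
    return get_recipe("SN", "SH", "hysteresis").build(curves)


class TestEulerMaruyama:
    def test_zero_noise_reduces_to_deterministic_euler(self, sn_sh_path):
        """With sigma = 0 the kernel must equal a plain Euler scheme; the
        oracle is a direct Python reimplementation of the update rule."""
        path = sn_sh_path
        cfg = IntegratorConfig(tstep=0.05, duration=25.0, sigma=0.0)
        res = integrate(path, config=cfg, label=False)
        # hand-rolled Euler on the same path
        from dynamotypes._kernels import stable_rest_root

        z = path.z_start
        p = path.params_at(z)
        x = float(stable_rest_root(p.mu1, p.mu2, p.nu, 0.0))
        y = 0.0
        hcfg = path.config
        track = x
        for i in range(cfg.n_steps):
            p = path.params_at(z)
            dx = -y
            dy = x**3 - p.mu2 * x - p.mu1 - y * (p.nu + x + x**2)
            track = float(stable_rest_root(p.mu1, p.mu2, p.nu, track))
            dist = np.hypot(x - track, y)
            dz = -hcfg.c * (dist - hcfg.d_star)
            x, y, z = x + 0.05 * dx, y + 0.05 * dy, z + 0.05 * dz
        assert res.x[-1] == pytest.approx(x, abs=1e-12)
        assert res.y[-1] == pytest.approx(y, abs=1e-12)
        assert res.z[-1] == pytest.approx(z, abs=1e-12)

    def test_first_order_convergence_in_tstep(self, sn_sh_path):
        """Richardson comparison at sigma = 0: halving the step changes the
        final state by O(tstep)."""
        T = 40.0
        errs = []
        steps = [0.08, 0.04, 0.02]
        finals = []
        for h in steps:
            res = integrate(
                sn_sh_path,
                config=IntegratorConfig(tstep=h, duration=T),
                label=False,
            )
            finals.append((res.x[-1], res.y[-1]))
        e1 = np.hypot(finals[0][0] - finals[1][0], finals[0][1] - finals[1][1])
        e2 = np.hypot(finals[1][0] - finals[2][0], finals[1][1] - finals[2][1])
        assert e1 > 0 and e2 > 0
        assert e1 / e2 == pytest.approx(2.0, rel=0.5)  # first order

    def test_bit_identical_reproducibility_with_noise(self, sn_sh_path):
        cfg = IntegratorConfig(tstep=0.05, duration=200.0, sigma=0.01, seed=5)
        r1 = integrate(sn_sh_path, config=cfg)
        r2 = integrate(sn_sh_path, config=cfg)
        assert np.array_equal(r1.x, r2.x)
        assert np.array_equal(r1.z, r2.z)
        r3 = integrate(
            sn_sh_path,
            config=IntegratorConfig(tstep=0.05, duration=200.0, sigma=0.01, seed=6),
        )
        assert not np.array_equal(r1.x, r3.x)

    def test_rest_state_spread_grows_with_sigma(self, sn_sh_path):
        """Ensemble standard deviation of x during rest grows monotonically
        with the noise amplitude (10-seed ensembles, 3 levels)."""
        spreads = []
        for sigma in (0.001, 0.01, 0.05):
            finals = []
            for seed in range(10):
                res = integrate(
                    sn_sh_path,
                    config=IntegratorConfig(
                        tstep=0.05, duration=60.0, sigma=sigma, seed=seed
                    ),
                    label=False,
                )
                finals.append(res.x[-1])
            spreads.append(np.std(finals))
        assert spreads[0] < spreads[1] < spreads[2]

    def test_noise_enters_x_only(self, sn_sh_path):
        cfg0 = IntegratorConfig(tstep=0.05, duration=5.0, sigma=0.0)
        cfg1 = IntegratorConfig(tstep=0.05, duration=5.0, sigma=0.05, seed=1)
        r0 = integrate(sn_sh_path, config=cfg0, label=False)
        r1 = integrate(sn_sh_path, config=cfg1, label=False)
        # after the very first step only x differs (y, z see noise only
        # indirectly from the second step on)
        assert r0.x[1] != r1.x[1]
        assert r0.y[1] == r1.y[1]
        assert r0.z[1] == r1.z[1]


class TestEventLabels:
    def test_hysteresis_onset_at_first_positive_z(self, sn_sh_path):
        res = integrate(sn_sh_path, config=IntegratorConfig(tstep=0.05, duration=8000))
        assert res.has_labels
        i0 = res.onset_index
        assert res.z[i0] > 0 and np.all(res.z[:i0] <= 0)
        assert res.z[res.offset_index] < res.path.z_offset
        assert res.onset_index < res.offset_index

    def test_monotone_z_without_crossing_flags_missing_labels(self, curves):
        path = get_recipe("SNIC", "SH", "slow_wave").build(curves)
        # too short to ever reach the onset crossing
        res = integrate(path, config=IntegratorConfig(tstep=0.05, duration=10.0))
        assert res.labels_flagged
        assert res.onset_index is None

    def test_slow_wave_onset_matches_geometric_crossing(self, curves):
        path = get_recipe("SNIC", "SH", "slow_wave").build(curves)
        dur = (path.z_offset - path.z_start) / path.config.k + 2000
        res = integrate(path, config=IntegratorConfig(tstep=0.05, duration=dur))
        assert res.has_labels
        # onset sample is where z crosses the onset-curve parameter (0)
        i0 = res.onset_index
        assert res.z[i0 - 1] <= path.z_onset < res.z[i0]
        assert res.z[res.offset_index] > path.z_offset

    def test_csv_round_trip(self, sn_sh_path, tmp_path):
        res = integrate(sn_sh_path, config=IntegratorConfig(tstep=0.05, duration=50.0))
        res.save_csv(tmp_path / "run")
        arr = np.loadtxt(tmp_path / "run.csv", delimiter=",", skiprows=1)
        assert np.allclose(arr[:, 1], res.x)
        import json

        side = json.loads((tmp_path / "run.json").read_text())
        assert side["config"]["tstep"] == 0.05
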