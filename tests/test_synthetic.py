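import numpy as np
import pytest

from gradscape.raster import Raster
from gradscape.sites import SiteSet, pair_index
from gradscape.synthetic import (MLPESimSpec, SurfaceSpec, classify_landcover,
                                 generate_surface, place_sites,
                                 simulate_microsatellites,
                                 simulate_mlpe_response)
from gradscape.gendist import rst_matrix


def psd_slope(values):
    """Independent periodogram-regression oracle for the spectral exponent."""
    z = values - values.mean()
    P = np.abs(np.fft.fft2(z)) ** 2
    n, m = z.shape
    fy = np.fft.fftfreq(n)[:, None] * n
    fx = np.fft.fftfreq(m)[None, :] * m
    r = np.round(np.hypot(np.broadcast_to(fy, P.shape),
                          np.broadcast_to(fx, P.shape))).astype(int)
    nyq = min(n, m) // 2
    sel = (r >= 2) & (r <= nyq // 2)
    counts = np.bincount(r[sel])
    with np.errstate(invalid="ignore"):
        radial = np.bincount(r[sel], weights=P[sel]) / counts
    radii = np.arange(len(radial))
    ok = counts > 0
    return np.polyfit(np.log(radii[ok]), np.log(radial[ok]), 1)[0]


class TestGenerateSurface:
    def test_deterministic_and_bounded(self):
        spec = SurfaceSpec(64, 64, 0.5, 30.0, seed=7)
        a, b = generate_surface(spec), generate_surface(spec)
        np.testing.assert_array_equal(a.values, b.values)
        assert a.values.min() >= 0.0 and a.values.max() <= 1.0

    def test_hurst_controls_roughness(self):
        smooth = generate_surface(SurfaceSpec(256, 256, 0.9, 30.0, seed=3))
        rough = generate_surface(SurfaceSpec(256, 256, 0.2, 30.0, seed=3))
        # increments of the smoother surface are smaller relative to range
        sa = lambda r: np.abs(np.diff(r.values, axis=1)).mean()
        assert sa(smooth) < sa(rough)
        # periodogram slope oracle: steeper decay for larger hurst
        assert psd_slope(smooth.values) < psd_slope(rough.values)

    @pytest.mark.parametrize("hurst", [0.3, 0.7])
    def test_psd_slope_matches_spec(self, hurst):
        surf = generate_surface(SurfaceSpec(256, 256, hurst, 30.0, seed=11))
        assert psd_slope(surf.values) == pytest.approx(-(2 * hurst + 2), abs=0.4)

    def test_invalid_spec(self):
        with pytest.raises(ValueError):
            SurfaceSpec(64, 64, 1.5, 30.0)
        with pytest.raises(ValueError):
            SurfaceSpec(8, 8, 0.5, 30.0)


class TestClassifyLandcover:
    def test_constant_high_all_forest(self):
        r = Raster(np.full((8, 8), 0.9), cell_size=30.0)
        out = classify_landcover(r, (0.3, 0.6))
        assert (out.values == 1).all()

    def test_uniform_thirds(self, rng):
        r = Raster(rng.random((100, 100)), cell_size=30.0)
        out = classify_landcover(r, (1 / 3, 2 / 3))
        n = out.values.size
        sigma = np.sqrt(n * (1 / 3) * (2 / 3))
        for cls in (1, 2, 3):
            assert abs((out.values == cls).sum() - n / 3) < 3 * sigma

    def test_break_order_enforced(self):
        r = Raster(np.full((4, 4), 0.5), cell_size=30.0)
        with pytest.raises(ValueError):
            classify_landcover(r, (0.7, 0.3))


class TestPlaceSites:
    def test_17_sites_136_pairs(self):
        r = Raster(np.zeros((256, 256)), cell_size=1.0)
        sites = place_sites(r, 17, min_sep=10.0, seed=1)
        assert len(pair_index(sites)) == 136
        c = sites.coords()
        d = np.hypot(c[:, 0][:, None] - c[:, 0], c[:, 1][:, None] - c[:, 1])
        assert d[np.triu_indices(17, 1)].min() >= 10.0

    def test_singleton(self):
        r = Raster(np.zeros((16, 16)), cell_size=1.0)
        assert place_sites(r, 1, min_sep=1.0, seed=0).n == 1

    def test_infeasible_raises(self):
        r = Raster(np.zeros((8, 8)), cell_size=1.0)
        with pytest.raises(RuntimeError, match="could not place"):
            place_sites(r, 3, min_sep=100.0, seed=0, max_attempts=200)

    def test_deterministic(self):
        r = Raster(np.zeros((64, 64)), cell_size=1.0)
        a = place_sites(r, 5, min_sep=5.0, seed=42)
        b = place_sites(r, 5, min_sep=5.0, seed=42)
        np.testing.assert_array_equal(a.coords(), b.coords())


class TestSimulateMLPEResponse:
    @pytest.fixture
    def sites(self):
        return SiteSet(list("abcdefgh"), np.arange(8.0), np.zeros(8))

    def test_noise_free_limit(self, sites, rng):
        X = rng.normal(size=(28, 2))
        spec = MLPESimSpec(np.array([0.5, 1.0, -2.0]), sigma_u=0.0,
                           sigma_e=1e-8, seed=0)
        y = simulate_mlpe_response(X, sites, spec)
        np.testing.assert_allclose(y, 0.5 + X @ [1.0, -2.0], atol=1e-6)

    def test_shared_site_covariance(self, sites):
        # cov(y_ij, y_ik) = sigma_u^2 for pairs sharing exactly site i
        pairs = pair_index(sites)
        i1 = pairs.index(("a", "b"))
        i2 = pairs.index(("a", "c"))
        draws = np.array([
            simulate_mlpe_response(np.zeros((28, 0)), sites,
                                   MLPESimSpec(np.array([0.0]), 1.0, 1.0, seed=s))
            for s in range(500)])
        cov = np.cov(draws[:, i1], draws[:, i2])[0, 1]
        # MC s.e. of a covariance of variance-2 variables over 500 draws
        assert cov == pytest.approx(1.0, abs=3 * 2.0 / np.sqrt(500))

    def test_deterministic(self, sites, rng):
        X = rng.normal(size=(28, 1))
        spec = MLPESimSpec(np.array([0.0, 1.0]), 0.5, 0.5, seed=9)
        np.testing.assert_array_equal(simulate_mlpe_response(X, sites, spec),
                                      simulate_mlpe_response(X, sites, spec))

    def test_dimension_mismatch(self, sites):
        with pytest.raises(ValueError, match="rows"):
            simulate_mlpe_response(np.zeros((5, 1)), sites,
                                   MLPESimSpec(np.array([0.0, 1.0])))


class TestSimulateMicrosatellites:
    def _sites(self, n, spacing=1000.0):
        return SiteSet([f"S{i}" for i in range(n)],
                       np.arange(n) * spacing, np.zeros(n))

    def test_panmixia_low_rst(self):
        sites = self._sites(5)
        vals = []
        for rep in range(5):
            g = simulate_microsatellites(sites, n_ind_per_site=25, n_loci=10,
                                         migration_scale=1e15,
                                         base_migration=0.3,
                                         n_generations=100, seed=rep)
            m = rst_matrix(g).to_numpy()
            vals.append(m[np.triu_indices(5, 1)].mean())
        assert np.mean(vals) <= 0.02

    def test_isolation_builds_differentiation(self):
        sites = self._sites(4)
        iso, pan = [], []
        for rep in range(3):
            gi = simulate_microsatellites(sites, 20, 8, migration_scale=1.0,
                                          n_generations=120, seed=rep)
            gp = simulate_microsatellites(sites, 20, 8, migration_scale=1e15,
                                          base_migration=0.3,
                                          n_generations=120, seed=rep)
            iso.append(rst_matrix(gi).to_numpy()[np.triu_indices(4, 1)].mean())
            pan.append(rst_matrix(gp).to_numpy()[np.triu_indices(4, 1)].mean())
        assert min(iso) > max(pan)

    def test_deterministic(self):
        sites = self._sites(3)
        a = simulate_microsatellites(sites, 5, 3, 1000.0, seed=4)
        b = simulate_microsatellites(sites, 5, 3, 1000.0, seed=4)
        assert a.equals(b)
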