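import numpy as np
import pytest

from plankgrid.geometry import km_to_degrees
from plankgrid.geostat import (
    EmpiricalVariogram,
    VariogramModel,
    block_mean_structured_variogram,
    consensus_lopt,
    detrend,
    empirical_variogram,
    fit_variogram,
    information_curve,
)
from plankgrid.synth import simulate_grf


def spherical_gamma(h, c1, a):
    """Independent closed-form spherical structured semivariance (oracle)."""
    h = np.asarray(h, dtype=float)
    out = np.where(h >= a, c1, c1 * (1.5 * h / a - 0.5 * (h / a) ** 3))
    return out


class TestDetrend:
    def test_linear_trend_removed_exactly(self, rng):
        pts = rng.uniform(0, 10, size=(40, 2))
        values = 2.0 + 3.0 * pts[:, 0]
        resid, _ = detrend(pts, values, order=1)
        assert np.max(np.abs(resid)) < 1e-9

    def test_order_zero_is_identity(self, rng):
        pts = rng.uniform(0, 10, size=(10, 2))
        values = rng.normal(size=10)
        resid, coef = detrend(pts, values, order=0)
        assert np.array_equal(resid, values)
        assert coef.size == 0

    def test_quadratic_residuals_orthogonal_to_design(self, rng):
        """Normal equations: OLS residuals are orthogonal to every column of
        the quadratic monomial design matrix."""
        pts = rng.uniform(0, 5, size=(60, 2))
        values = rng.normal(size=60)
        resid, _ = detrend(pts, values, order=2)
        x, y = pts[:, 0], pts[:, 1]
        for col in (np.ones(60), x, y, x * y, x**2, y**2):
            assert abs(resid @ col) < 1e-6


class TestEmpiricalVariogram:
    def test_constant_field_gives_zero(self, rng):
        pts = rng.uniform(0, 10, size=(20, 2))
        emp = empirical_variogram(pts, np.full(20, 3.7), n_lags=5, max_lag=20.0)
        assert np.all(emp.gamma_hat == 0.0)

    def test_two_points_single_bin(self):
        pts = np.array([[0.0, 0.0], [1.0, 0.0]])
        emp = empirical_variogram(pts, np.array([0.0, 2.0]), n_lags=1, max_lag=2.0)
        assert emp.gamma_hat[0] == pytest.approx(2.0)
        assert emp.n_pairs[0] == 1

    def test_matches_brute_force_pair_enumeration(self, rng):
        """Five points: every bin's semivariance equals the direct sum over
        enumerated unordered pairs."""
        pts = rng.uniform(0, 10, size=(5, 2))
        z = rng.normal(size=5)
        n_lags, max_lag = 4, 16.0
        emp = empirical_variogram(pts, z, n_lags=n_lags, max_lag=max_lag)
        edges = np.linspace(0, max_lag, n_lags + 1)
        sums = np.zeros(n_lags)
        counts = np.zeros(n_lags)
        for i in range(5):
            for j in range(i + 1, 5):
                d = np.hypot(*(pts[i] - pts[j]))
                if d <= 0 or d > max_lag:
                    continue
                b = np.searchsorted(edges, d, side="left") - 1
                sums[b] += 0.5 * (z[i] - z[j]) ** 2
                counts[b] += 1
        keep = counts > 0
        assert np.allclose(emp.gamma_hat, sums[keep] / counts[keep])
        assert np.array_equal(emp.n_pairs, counts[keep].astype(int))


class TestFitVariogram:
    def _noiseless(self, family, c0, c1, a, h):
        model = VariogramModel(family, c0, c1, a)
        return EmpiricalVariogram(h, model.gamma(h), np.full(len(h), 50))

    def test_recovers_noiseless_spherical(self):
        h = np.linspace(5, 120, 12)
        fit = fit_variogram(self._noiseless("spherical", 1.0, 4.0, 50.0, h), "spherical")
        assert fit.nugget == pytest.approx(1.0, rel=1e-4, abs=1e-4)
        assert fit.partial_sill == pytest.approx(4.0, rel=1e-4)
        assert fit.range_km == pytest.approx(50.0, rel=1e-4)

    def test_recovers_noiseless_exponential(self):
        h = np.linspace(5, 120, 12)
        fit = fit_variogram(
            self._noiseless("exponential", 0.5, 2.0, 40.0, h), "exponential"
        )
        assert fit.nugget == pytest.approx(0.5, rel=1e-3, abs=1e-3)
        assert fit.partial_sill == pytest.approx(2.0, rel=1e-3)
        assert fit.range_km == pytest.approx(40.0, rel=1e-3)

    def test_flat_variogram_fits_pure_nugget(self):
        h = np.linspace(5, 100, 8)
        emp = EmpiricalVariogram(h, np.full(8, 2.0), np.full(8, 30))
        fit = fit_variogram(emp, "spherical")
        assert fit.nugget + fit.partial_sill == pytest.approx(2.0, abs=0.01)
        assert fit.partial_sill < 0.05 or fit.nugget == pytest.approx(2.0, abs=0.05)

    def test_parameter_recovery_from_simulated_fields(self):
        """Median fitted range within ±25% and median nugget fraction within
        ±0.15 over 20 replicate fields (n=300, spherical 0.3/1.0/60)."""
        model = VariogramModel("spherical", 0.3, 1.0, 60.0)
        rng = np.random.default_rng(77)
        ranges, fracs = [], []
        for rep in range(20):
            pts = rng.uniform(0, 400, size=(300, 2))
            z = simulate_grf(pts, model, seed=500 + rep)
            emp = empirical_variogram(pts, z, n_lags=15)
            fit = fit_variogram(emp, "spherical")
            ranges.append(fit.range_km)
            fracs.append(fit.nugget / max(fit.sill, 1e-12))
        assert abs(np.median(ranges) - 60.0) / 60.0 < 0.25
        assert abs(np.median(fracs) - 0.3 / 1.3) < 0.15


class TestBlockMean:
    MODEL = VariogramModel("spherical", 0.0, 1.0, 50.0)

    def test_vanishes_for_tiny_cells(self):
        assert block_mean_structured_variogram(self.MODEL, 50.0 / 1e6, 10) < 1e-4

    def test_reaches_sill_for_huge_cells(self):
        val = block_mean_structured_variogram(self.MODEL, 500.0, 10)
        assert val == pytest.approx(1.0, rel=0.02)

    def test_matches_brute_force_lattice(self):
        """Direct double-sum over the lattice, written independently."""
        m, v = 10, 50.0
        ticks = (np.arange(m) + 0.5) / m * v
        total, count = 0.0, 0
        for ix in range(m * m):
            for iy in range(ix + 1, m * m):
                p = np.array([ticks[ix % m], ticks[ix // m]])
                q = np.array([ticks[iy % m], ticks[iy // m]])
                h = np.hypot(*(p - q))
                total += spherical_gamma(h, 1.0, 50.0)
                count += 1
        oracle = total / count
        assert block_mean_structured_variogram(self.MODEL, v, m) == pytest.approx(
            oracle, rel=1e-12
        )

    def test_discretization_converges(self):
        coarse = block_mean_structured_variogram(self.MODEL, 50.0, 10)
        fine = block_mean_structured_variogram(self.MODEL, 50.0, 40)
        assert coarse == pytest.approx(fine, rel=0.02)


class TestInformationCurve:
    def test_single_station_cells_carry_no_information(self):
        model = VariogramModel("spherical", 1.0, 1.0, 60.0)
        curve = information_curve(model, 0.002, (5.0, 20.0, 1.0))
        assert np.all(curve.n_bar[curve.v**2 * 0.002 <= 1.0] == 1.0)
        assert np.all(curve.f[curve.n_bar == 1.0] == 0.0)

    def test_pure_nugget_prefers_largest_cell(self):
        model = VariogramModel("spherical", 2.0, 0.0, 60.0)
        curve = information_curve(model, 0.002, (5.0, 200.0, 0.5))
        assert np.all(curve.PS == 1.0)
        assert curve.Lopt == 200.0

    def test_lopt_matches_fine_grid_brute_force(self):
        """Lopt agrees with an independently coded exhaustive search at a
        50x finer step, within one coarse step."""
        model = VariogramModel("spherical", 1.0, 1.0, 60.0)
        density, step = 0.002, 0.5
        curve = information_curve(model, density, (5.0, 200.0, step))
        vs = np.arange(5.0, 200.0 + 0.005, 0.01)
        # oracle: own lattice-distance cache and spherical formula
        m = 10
        ticks = (np.arange(m) + 0.5) / m
        xx, yy = np.meshgrid(ticks, ticks)
        P = np.column_stack([xx.ravel(), yy.ravel()])
        du = np.sqrt(((P[:, None, :] - P[None, :, :]) ** 2).sum(-1))
        du = du[np.triu_indices(m * m, 1)]
        f = np.empty_like(vs)
        for i, v in enumerate(vs):
            nbar = max(1.0, density * v * v)
            PN = 1.0 - 1.0 / nbar
            PS = 1.0 - spherical_gamma(v * du, 1.0, 60.0).mean() / 1.0
            f[i] = PN * max(PS, 0.0)
        v_star = vs[np.argmax(f)]
        assert abs(curve.Lopt - v_star) <= step

    def test_pn_nondecreasing_ps_nonincreasing(self):
        model = VariogramModel("exponential", 0.4, 1.5, 45.0)
        curve = information_curve(model, 0.001, (5.0, 200.0, 0.5))
        assert np.all(np.diff(curve.PN) >= -1e-12)
        assert np.all(np.diff(curve.PS) <= 1e-12)
        assert np.allclose(curve.f, curve.PN * curve.PS)

    def test_lopt_monotone_in_true_range(self):
        """Longer-range spatial structure permits larger cells: median Lopt
        (10 seeds, fit on n=300 simulated fields) does not decrease with a."""
        medians = []
        rng = np.random.default_rng(31)
        for a in (30.0, 60.0, 120.0):
            model = VariogramModel("spherical", 0.3, 1.0, a)
            lopts = []
            for rep in range(10):
                pts = rng.uniform(0, 400, size=(300, 2))
                z = simulate_grf(pts, model, seed=int(a) * 100 + rep)
                fit = fit_variogram(empirical_variogram(pts, z, n_lags=15), "spherical")
                curve = information_curve(fit, 300 / 400**2, (5.0, 200.0, 1.0))
                lopts.append(curve.Lopt)
            medians.append(np.median(lopts))
        assert medians[0] <= medians[1] <= medians[2]


class TestConsensusLopt:
    def _curve(self, lopt, f=0.5):
        v = np.array([lopt - 1, lopt, lopt + 1], dtype=float)
        fs = np.array([f * 0.9, f, f * 0.9])
        return type(
            "C", (), {"Lopt": lopt, "f_at_Lopt": f, "v": v, "f": fs,
                      "f_at": lambda self, vv: float(np.interp(vv, v, fs))}
        )()

    def test_single_taxon_is_its_own_consensus(self):
        out = consensus_lopt({"t": self._curve(80.0)})
        assert out.consensus == 80.0
        assert out.max_relative_f_loss == 0.0

    def test_median_of_three(self):
        out = consensus_lopt(
            {"a": self._curve(80.0), "b": self._curve(92.0), "c": self._curve(123.0)}
        )
        assert out.consensus == 92.0

    def test_loss_evaluated_on_each_taxons_curve(self):
        from plankgrid.geostat import InformationCurve

        curves = {}
        for name, a in (("short", 30.0), ("mid", 60.0), ("long", 120.0)):
            model = VariogramModel("spherical", 0.3, 1.0, a)
            curves[name] = information_curve(model, 0.002, (5.0, 200.0, 0.5))
        out = consensus_lopt(curves)
        expected = max(
            max(0.0, (c.f_at_Lopt - np.interp(out.consensus, c.v, c.f)) / c.f_at_Lopt)
            for c in curves.values()
        )
        assert out.max_relative_f_loss == pytest.approx(expected, rel=1e-9)


class TestKmToDegrees:
    @pytest.mark.parametrize(
        "km,deg", [(91.58, 0.83), (110.574, 1.00), (55.287, 0.50)]
    )
    def test_latitude_degree_conversion(self, km, deg):
        assert km_to_degrees(km) == deg
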