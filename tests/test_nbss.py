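import numpy as np
import pytest
from scipy import stats

from nbssbench import nbss, spectra as sp
from nbssbench.spectra import NormalizedSpectrum
from tests.conftest import make_grab, make_record


def equal_biomass_spectrum(b: float = 64.0, lo: int = 0, hi: int = 15):
    """Each class holds total biomass b exactly (one weighted record)."""
    recs = []
    for n in range(lo, hi + 1):
        m = 1.5 * 2.0**n
        recs.append(make_record(m, count=b / m))
    return sp.build_spectrum(make_grab(recs))


class TestFitNBSS:
    def test_equal_biomass_gives_slope_minus_one(self):
        norm = sp.normalize(equal_biomass_spectrum(b=2.0**16))
        fit = nbss.fit_nbss(norm)
        assert fit.slope == pytest.approx(-1.0, abs=1e-12)
        assert fit.r2 == pytest.approx(1.0, abs=1e-12)

    def test_one_organism_of_mass_2n_per_class_gives_slope_zero(self):
        classes = {n: 2.0**n for n in range(0, 12)}  # biomass = class floor
        norm = NormalizedSpectrum(classes={n: b / sp.class_width(n) for n, b in classes.items()})
        fit = nbss.fit_nbss(norm)
        assert fit.slope == pytest.approx(0.0, abs=1e-12)
        assert fit.intercept == pytest.approx(0.0, abs=1e-12)

    def test_requires_three_positive_points(self):
        with pytest.raises(ValueError):
            nbss.fit_nbss((np.array([0.0, 1.0]), np.array([1.0, 2.0])))
        with pytest.raises(ValueError):
            nbss.fit_nbss((np.arange(4.0), np.array([1.0, 2.0, 0.0, 3.0])))

    def test_affine_equivariance(self, rng):
        ns = np.arange(-5.0, 10.0)
        nb = 2.0 ** (8.0 - 0.6 * ns + rng.normal(0, 0.4, ns.size))
        base = nbss.fit_nbss((ns, nb))
        k = 7.3
        scaled = nbss.fit_nbss((ns, k * nb))
        assert scaled.slope == pytest.approx(base.slope, rel=1e-10)
        assert scaled.intercept == pytest.approx(base.intercept + np.log2(k), rel=1e-10)

    def test_monte_carlo_slope_coverage(self, rng):
        """Slope estimates from noisy spectra cover the generating value.

        The +/- 2 SE band has nominal coverage ~95.1% (t, 82 df); the
        observed rate over 2000 replicates must sit in a band around it.
        """
        true_slope, true_int, sd = -0.53, 11.0, 0.5
        ns = np.tile(np.arange(-11.0, 17.0), 3)  # 28 classes x 3 stations
        X = np.column_stack([np.ones_like(ns), ns])
        xtx_inv = np.linalg.inv(X.T @ X)
        hits = 0
        reps = 2000
        for _ in range(reps):
            y = true_int + true_slope * ns + rng.normal(0, sd, ns.size)
            beta = xtx_inv @ X.T @ y
            resid = y - X @ beta
            s2 = resid @ resid / (ns.size - 2)
            se = np.sqrt(s2 * xtx_inv[1, 1])
            hits += abs(beta[1] - true_slope) < 2 * se
        assert 0.94 <= hits / reps <= 0.97

    def test_ci_coverage_nominal_rate(self, rng):
        """95% CIs for slope and intercept cover (-0.53, 11.0) at 95% +/- 3%."""
        true = np.array([11.0, -0.53])
        ns = np.tile(np.arange(-11.0, 17.0), 3)
        X = np.column_stack([np.ones_like(ns), ns])
        xtx_inv = np.linalg.inv(X.T @ X)
        tcrit = stats.t.ppf(0.975, ns.size - 2)
        cover = np.zeros(2)
        reps = 1000
        for _ in range(reps):
            y = X @ true + rng.normal(0, 0.5, ns.size)
            beta = xtx_inv @ X.T @ y
            resid = y - X @ beta
            s2 = resid @ resid / (ns.size - 2)
            se = np.sqrt(s2 * np.diag(xtx_inv))
            cover += np.abs(beta - true) < tcrit * se
        rates = cover / reps
        assert np.all(rates > 0.92) and np.all(rates < 0.98)


class TestDiagnostics:
    def test_perfect_line_unflagged(self):
        ns = np.arange(0.0, 20.0)
        fit = nbss.fit_nbss((ns, 2.0 ** (10 - 0.8 * ns)))
        diag = nbss.diagnose_fit(fit)
        assert diag.influential == []
        assert diag.threshold == pytest.approx(4.0 / 20.0)

    def test_gross_outlier_at_top_class_flagged(self, rng):
        ns = np.arange(0.0, 20.0)
        y = 10 - 0.8 * ns + rng.normal(0, 0.2, ns.size)
        y[-1] += 6.0  # gross outlier in the highest class
        fit = nbss.fit_nbss((ns, 2.0**y))
        diag = nbss.diagnose_fit(fit)
        flagged_classes = [n for n, _ in diag.influential]
        assert 19 in flagged_classes
        assert diag.extreme_class_flagged

    def test_outlier_agrees_with_leave_one_out_influence(self, rng):
        ns = np.arange(0.0, 15.0)
        y = 8 - 0.6 * ns + rng.normal(0, 0.15, ns.size)
        y[0] -= 4.0
        fit = nbss.fit_nbss((ns, 2.0**y))
        # leave-one-out slope shifts, scaled, identify the same worst point
        shifts = []
        for i in range(ns.size):
            keep = np.arange(ns.size) != i
            loo = nbss.fit_nbss((ns[keep], 2.0 ** y[keep]))
            shifts.append(abs(loo.slope - fit.slope))
        assert int(np.argmax(fit.cooks_d)) == int(np.argmax(shifts)) == 0


class TestCompareSlopes:
    def _group(self, rng, slope, intercept, sd=0.3, lo=-5, hi=15):
        ns = np.arange(float(lo), float(hi) + 1)
        return ns, 2.0 ** (intercept + slope * ns + rng.normal(0, sd, ns.size))

    def test_null_interaction_p_uniform(self, rng):
        """Identical generating lines: interaction p is U(0,1) (KS, alpha=.01)."""
        ps = []
        for _ in range(1000):
            g1 = self._group(rng, -0.7, 9.0)
            g2 = self._group(rng, -0.7, 9.0)
            comp = nbss.compare_slopes({"a": g1, "b": g2})
            ps.append(comp.p_interaction)
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_distinct_slopes_detected_with_high_power(self, rng):
        rejections = 0
        for _ in range(100):
            g1 = self._group(rng, -0.5, 9.0, sd=0.1)
            g2 = self._group(rng, -1.0, 9.0, sd=0.1)
            comp = nbss.compare_slopes({"a": g1, "b": g2})
            rejections += comp.p_interaction < 0.05
        assert rejections >= 99

    def test_intercept_shift_found_when_slopes_equal(self, rng):
        groups = {}
        for i in range(6):
            shift = 2.0 if i == 2 else 0.0
            groups[f"g{i}"] = [self._group(rng, -0.6, 9.0 + shift, sd=0.3) for _ in range(3)]
        comp = nbss.compare_slopes(groups)
        assert comp.p_interaction > 0.05
        pw = nbss.pairwise_intercepts(comp)
        hits = pw[(pw.group_i == "g2") | (pw.group_j == "g2")]
        assert (hits.p_adj < 0.05).all()
        assert comp.intercepts["g2"][0] - comp.intercepts["g0"][0] == pytest.approx(2.0, abs=0.5)

    def test_single_group_reduces_to_fit_nbss(self, rng):
        ns, nb = self._group(rng, -0.6, 9.0)
        comp = nbss.compare_slopes({"only": (ns, nb)})
        fit = nbss.fit_nbss((ns, nb))
        assert comp.common_slope == pytest.approx(fit.slope, rel=1e-10)
        assert comp.common_slope_se == pytest.approx(fit.slope_se, rel=1e-10)
        assert comp.intercepts["only"][0] == pytest.approx(fit.intercept, rel=1e-10)
        assert comp.intercepts["only"][1] == pytest.approx(fit.intercept_se, rel=1e-10)

    def test_df_accounting(self, rng):
        groups = {f"g{i}": self._group(rng, -0.6, 9.0) for i in range(3)}
        comp = nbss.compare_slopes(groups)
        assert comp.df_num == 2
        assert comp.df_den == comp.n_points - 2 * 3


class TestPairwise:
    def test_two_groups_adjusted_equals_t_test(self, rng):
        ns = np.arange(-5.0, 15.0)
        groups = {
            "a": (ns, 2.0 ** (9.0 - 0.6 * ns + rng.normal(0, 0.3, ns.size))),
            "b": (ns, 2.0 ** (9.5 - 0.6 * ns + rng.normal(0, 0.3, ns.size))),
        }
        comp = nbss.compare_slopes(groups)
        pw = nbss.pairwise_intercepts(comp)
        t = pw.loc[0, "t"]
        p_t = 2 * stats.t.sf(abs(t), comp.df_resid_common)
        assert pw.loc[0, "p_adj"] == pytest.approx(p_t, rel=1e-6)

    def test_adjustment_is_conservative(self, rng):
        ns = np.arange(-5.0, 15.0)
        groups = {
            f"g{i}": (ns, 2.0 ** (9.0 - 0.6 * ns + rng.normal(0, 0.3, ns.size)))
            for i in range(5)
        }
        comp = nbss.compare_slopes(groups)
        pw = nbss.pairwise_intercepts(comp)
        p_unadj = 2 * stats.t.sf(np.abs(pw.t), comp.df_resid_common)
        assert (pw.p_adj.to_numpy() >= p_unadj - 1e-12).all()
        assert (pw.p_adj > 0.05).all()  # identical groups: nothing significant

    def test_far_shifted_group_significant_everywhere(self, rng):
        ns = np.arange(-5.0, 15.0)
        groups = {
            f"g{i}": (ns, 2.0 ** ((12.0 if i == 0 else 9.0) - 0.6 * ns
                                  + rng.normal(0, 0.3, ns.size)))
            for i in range(4)
        }
        pw = nbss.pairwise_intercepts(nbss.compare_slopes(groups))
        hits = pw[(pw.group_i == "g0") | (pw.group_j == "g0")]
        others = pw[(pw.group_i != "g0") & (pw.group_j != "g0")]
        assert (hits.p_adj < 0.01).all()
        assert (others.p_adj > 0.05).all()


class TestInterceptBiomassCorrelation:
    def _spectrum(self, intercept, station, hi=12):
        recs = []
        for n in range(-3, hi):
            b = 2.0 ** (intercept - 0.6 * n + n)
            m = 1.5 * 2.0**n
            recs.append(make_record(m, count=b / m))
        return sp.build_spectrum(make_grab(recs, station=station))

    def test_monotone_association_gives_rho_one(self):
        specs = [self._spectrum(8.0 + 0.3 * i, f"S{i}") for i in range(6)]
        res = nbss.intercept_biomass_correlation(specs)
        assert res.rho_total_dm == pytest.approx(1.0)

    def test_antimonotone_gives_rho_minus_one(self):
        # larger intercept but radically shrinking class range -> smaller totals
        specs = [self._spectrum(8.0 + 0.3 * i, f"S{i}", hi=12 - 2 * i) for i in range(6)]
        totals = [s.total_biomass_ug for s in specs]
        assert np.argsort(totals).tolist() == list(range(5, -1, -1))
        res = nbss.intercept_biomass_correlation(specs)
        assert res.rho_total_dm == pytest.approx(-1.0)

    def test_requires_five_stations_and_nonconstant_values(self):
        specs = [self._spectrum(8.0, f"S{i}") for i in range(4)]
        with pytest.raises(ValueError):
            nbss.intercept_biomass_correlation(specs)
        same = [self._spectrum(8.0, f"S{i}") for i in range(6)]
        with pytest.raises(ValueError, match="constant"):
            nbss.intercept_biomass_correlation(same)

    def test_truncation_to_common_range_strengthens_association(self):
        """Varying station class ranges decorrelate intercepts from totals;
        restricting to the common range restores the association."""
        from nbssbench import pipeline
        from nbssbench.synthetic_data import ScenarioConfig, generate_community

        full, truncated = [], []
        for seed in range(200):
            cfg = ScenarioConfig(seed=90_000 + seed)
            samples, _, _ = generate_community(cfg)
            specs = list(pipeline.station_spectra(pipeline.convert_samples(samples)).values())
            full.append(nbss.intercept_biomass_correlation(specs).rho_total_dm)
            truncated.append(
                nbss.intercept_biomass_correlation(specs, class_range=(-10, 14)).rho_total_dm
            )
        assert np.mean(truncated) > np.mean(full)
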