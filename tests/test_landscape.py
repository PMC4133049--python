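import numpy as np
import pytest
from sklearn.base import clone

from fatescape import (
    EpigeneticLandscape,
    FatePanel,
    SyntheticSpec,
    correlation_matrix,
    culture_fields,
    dev_coupling,
    interaction_matrix,
    local_field,
    overlaps,
    predictivity_matrix,
    projections,
    synth_fate_panel,
    total_energy,
)
from fatescape.errors import (
    DimensionMismatchError,
    SingularCorrelationError,
    ValidationError,
)


class TestCorrelationMatrix:
    def test_orthogonal_fates_give_identity(self, ortho_panel):
        corr = correlation_matrix(ortho_panel)
        assert np.allclose(corr.a, np.eye(2))
        assert np.allclose(corr.a @ corr.a_inv, np.eye(2), atol=1e-8)

    def test_hand_computed_half_correlation(self, correlated_panel):
        corr = correlation_matrix(correlated_panel)
        assert np.allclose(corr.a, [[1, 0.5], [0.5, 1]])
        assert np.all(np.diag(corr.a) == 1.0)
        assert corr.condition_number == pytest.approx(3.0)

    def test_duplicate_fates_rejected_by_name(self):
        xi = np.array([[1, 1], [-1, -1], [1, 1]])
        panel = FatePanel(("a", "b", "c"), ("left", "right"), xi)
        with pytest.raises(SingularCorrelationError, match="left.*right"):
            correlation_matrix(panel)

    def test_antipodal_fates_rejected(self):
        xi = np.array([[1, -1], [-1, 1], [1, -1]])
        panel = FatePanel(("a", "b", "c"), ("up", "down"), xi)
        with pytest.raises(SingularCorrelationError, match="antipodal"):
            correlation_matrix(panel)


class TestOverlapsAndProjections:
    def test_pure_and_flipped_patterns(self, correlated_panel):
        corr = correlation_matrix(correlated_panel)
        xi = np.asarray(correlated_panel.xi, dtype=float)
        assert overlaps(correlated_panel, xi[:, 0])[0] == pytest.approx(1.0)
        assert overlaps(correlated_panel, -xi[:, 0])[0] == pytest.approx(-1.0)
        # hand-derived: S = xi^B has m = (0.5, 1) and a = (0, 1)
        m = overlaps(correlated_panel, xi[:, 1])
        assert np.allclose(m, [0.5, 1.0])
        assert np.allclose(projections(corr, m), [0.0, 1.0], atol=1e-9)

    def test_projection_is_indicator_on_every_fate(self, fitted):
        a = fitted.transform(fitted.xi_.T)
        assert np.allclose(a, np.eye(fitted.xi_.shape[1]), atol=1e-9)

    def test_projection_equals_least_squares_coefficients(self, fitted):
        rng = np.random.default_rng(10)
        states = rng.choice([-1.0, 1.0], size=(20, fitted.n_features_in_))
        a = fitted.transform(states)
        coef, *_ = np.linalg.lstsq(fitted.xi_, states.T, rcond=None)
        assert np.allclose(a, coef.T, atol=1e-8)

    def test_length_mismatch_rejected(self, fitted):
        with pytest.raises(DimensionMismatchError):
            fitted.overlaps(np.ones(3))


class TestCouplings:
    def test_single_pattern_hand_value(self):
        xi = np.array([[1], [1], [-1]])  # N=3 so N > p
        panel = FatePanel(("a", "b", "c"), ("only",), xi)
        corr = correlation_matrix(panel)
        j = interaction_matrix(panel, corr)
        assert np.allclose(j, np.outer(xi[:, 0], xi[:, 0]) / 3)
        assert np.allclose(j @ xi[:, 0], xi[:, 0])

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_projector_identities(self, seed):
        panel = synth_fate_panel(SyntheticSpec(n_tfs=150, n_fates=6, seed=seed))
        corr = correlation_matrix(panel)
        j = interaction_matrix(panel, corr)
        xi = np.asarray(panel.xi, dtype=float)
        assert np.allclose(j, j.T, atol=1e-8)
        assert np.allclose(j @ j, j, atol=1e-8)
        assert np.trace(j) == pytest.approx(6.0, abs=1e-6)
        assert np.allclose(j @ xi, xi, atol=1e-8)


class TestControlFields:
    def test_zero_bias_gives_zero_field(self, fitted):
        assert np.allclose(fitted.culture_field(np.zeros(5)), 0.0)

    def test_orthogonal_unit_bias_returns_the_pattern(self, ortho_panel):
        corr = correlation_matrix(ortho_panel)
        b = culture_fields(ortho_panel, corr, np.array([0.0, 1.0]))
        assert np.allclose(b, np.asarray(ortho_panel.xi)[:, 1])

    def test_field_energy_matches_projection_energy(self, fitted):
        rng = np.random.default_rng(11)
        c = rng.normal(size=5)
        b = fitted.culture_field(c)
        n = fitted.n_features_in_
        for gamma in range(5):
            # -b . xi^gamma == -N c_gamma (since a(xi^gamma) is the indicator)
            assert -b @ fitted.xi_[:, gamma] == pytest.approx(-n * c[gamma], abs=1e-6)

    def test_dev_coupling_direction_convention(self, ortho_panel):
        corr = correlation_matrix(ortho_panel)
        d = np.zeros((2, 2))
        d[1, 0] = 0.7  # open a path from fate A (index 0) to fate B (index 1)
        jd = dev_coupling(ortho_panel, corr, d)
        xi = np.asarray(ortho_panel.xi, dtype=float)
        field = jd @ xi[:, 0]
        assert np.allclose(field, 0.7 * xi[:, 1], atol=1e-9)
        assert not np.allclose(jd, jd.T)

    def test_zero_signal_is_zero_coupling(self, fitted):
        assert np.allclose(fitted.dev_coupling(np.zeros((5, 5))), 0.0)

    def test_dimension_mismatches_rejected(self, fitted):
        with pytest.raises(DimensionMismatchError):
            fitted.culture_field(np.zeros(3))
        with pytest.raises(DimensionMismatchError):
            fitted.dev_coupling(np.zeros((2, 2)))


class TestEnergy:
    def test_every_fate_is_an_equally_deep_basin(self, fitted):
        n = fitted.n_features_in_
        for k in range(fitted.xi_.shape[1]):
            e = fitted.energy(fitted.xi_[:, k])
            assert e.h_basin == pytest.approx(-n / 2, abs=1e-8)
            # direct summation oracle
            s = fitted.xi_[:, k]
            direct = -0.5 * sum(
                fitted.coupling_[i, j] * s[i] * s[j] for i in range(n) for j in range(n)
            )
            assert e.h_basin == pytest.approx(direct, abs=1e-8)
            assert e.h_total == e.h_basin  # no fields

    def test_basin_energy_bounded_below_and_flip_symmetric(self, fitted):
        rng = np.random.default_rng(12)
        n = fitted.n_features_in_
        states = rng.choice([-1.0, 1.0], size=(50, n))
        for s in states:
            e = fitted.energy(s)
            assert e.h_basin >= -n / 2 - 1e-9
            assert fitted.energy(-s).h_basin == pytest.approx(e.h_basin, abs=1e-9)

    def test_breakdown_sums_and_field_terms(self, fitted):
        rng = np.random.default_rng(13)
        n = fitted.n_features_in_
        s = rng.choice([-1.0, 1.0], size=n)
        b_opt = rng.normal(size=n)
        c = rng.normal(size=5)
        d = rng.normal(size=(5, 5))
        e = fitted.energy(s, b_opt=b_opt, c=c, d=d)
        assert e.h_total == pytest.approx(e.h_basin + e.h_opt + e.h_culture + e.h_dev, abs=1e-9)
        assert e.h_opt == pytest.approx(-b_opt @ s)
        a = fitted.transform(s)
        m = fitted.overlaps(s)
        assert e.h_culture == pytest.approx(-n * c @ a, abs=1e-8)
        assert e.h_dev == pytest.approx(-n * a @ d @ m, abs=1e-8)


class TestLocalField:
    def test_full_field_reproduces_the_pattern(self, fitted):
        for k in range(5):
            h = fitted.local_field(fitted.xi_[:, k])
            assert np.allclose(h, fitted.xi_[:, k], atol=1e-9)

    def test_overexpression_shifts_only_the_targeted_tf(self, fitted):
        n = fitted.n_features_in_
        s = fitted.xi_[:, 0]
        b = np.zeros(n)
        b[3] = 2.5
        h0 = fitted.local_field(s)
        h1 = fitted.local_field(s, b_opt=b)
        assert h1[3] == pytest.approx(h0[3] + 2.5)
        mask = np.arange(n) != 3
        assert np.allclose(h1[mask], h0[mask])

    def test_single_flip_energy_identity(self):
        # for symmetric couplings and D = 0, dH = 2 S_i h_i with the
        # self-coupling-excluded field; checked exhaustively on a small panel
        panel = synth_fate_panel(SyntheticSpec(n_tfs=10, n_fates=2, seed=33))
        land = EpigeneticLandscape().fit(panel)
        rng = np.random.default_rng(14)
        b_opt = rng.normal(size=10)
        c = rng.normal(size=2)
        s = rng.choice([-1.0, 1.0], size=10)
        h = land.local_field(s, b_opt=b_opt, c=c, exclude_self=True)
        e0 = land.energy(s, b_opt=b_opt, c=c).h_total
        for i in range(10):
            s2 = s.copy()
            s2[i] = -s2[i]
            de = land.energy(s2, b_opt=b_opt, c=c).h_total - e0
            assert de == pytest.approx(2 * s[i] * h[i], abs=1e-9)

    def test_dimension_mismatch_rejected(self, fitted):
        with pytest.raises(DimensionMismatchError):
            local_field(np.ones(4), fitted.coupling_)


class TestPredictivity:
    def test_orthogonal_panel_predictivity_equals_patterns(self, ortho_panel):
        corr = correlation_matrix(ortho_panel)
        p = predictivity_matrix(ortho_panel, corr)
        assert np.allclose(p, np.asarray(ortho_panel.xi, dtype=float))

    def test_projection_reconstruction_identity(self, fitted):
        rng = np.random.default_rng(15)
        states = rng.choice([-1.0, 1.0], size=(100, fitted.n_features_in_))
        a_direct = fitted.transform(states)
        a_from_p = states @ fitted.predictivity_ / fitted.n_features_in_
        assert np.abs(a_direct - a_from_p).max() < 1e-8

    def test_normalization_identity(self, fitted):
        n = fitted.n_features_in_
        gram = fitted.xi_.T @ fitted.predictivity_ / n
        assert np.allclose(gram, np.eye(5), atol=1e-8)

    def test_planted_unique_marker_is_highly_predictive(self):
        # lineage-correlated panel: predictivity must discount shared signal
        # and promote the fate-specific marker
        panel = synth_fate_panel(
            SyntheticSpec(n_tfs=400, n_fates=8, flip_prob=0.25, seed=44)
        )
        xi = np.asarray(panel.xi).copy()
        xi[0, :] = -1
        xi[0, 2] = 1  # TF 0 is on only in fate 2
        marked = FatePanel(panel.tf_ids, panel.fate_names, xi)
        land = EpigeneticLandscape().fit(marked)
        ranks = np.argsort(-land.predictivity_[:, 2])
        assert np.flatnonzero(ranks == 0)[0] < 40  # top decile of 400


class TestEstimatorContract:
    def test_fit_from_array_and_sklearn_protocol(self):
        rng = np.random.default_rng(17)
        X = rng.choice([-1, 1], size=(3, 40))  # p=3 patterns as rows
        est = EpigeneticLandscape(max_condition=1e10)
        assert clone(est).get_params() == est.get_params()
        est.fit(X)
        assert est.n_features_in_ == 40
        assert est.coupling_.shape == (40, 40)
        assert est.transform(X).shape == (3, 3)

    def test_unfitted_rejected(self):
        with pytest.raises(ValidationError):
            EpigeneticLandscape().overlaps(np.ones(4))

    def test_pseudo_inverse_escape_hatch(self):
        xi = np.array([[1, 1], [-1, -1], [1, 1], [-1, -1], [1, -1]])
        # nearly duplicate fates: condition number is large but finite
        panel = FatePanel(tuple("abcde"), ("F0", "F1"), xi)
        with pytest.raises(SingularCorrelationError):
            EpigeneticLandscape(max_condition=2.0).fit(panel)
        est = EpigeneticLandscape(max_condition=2.0, pseudo_inverse=True).fit(panel)
        assert np.isfinite(est.correlation_inv_).all()
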