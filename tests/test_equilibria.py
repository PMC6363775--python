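"""Interior equilibria, boundary stability, phase classes, and bifurcations."""

import numpy as np
import pytest

from pggdyn import (
    ModelParams,
    bifurcation_sweep,
    boundary_states,
    classify_dynamics,
    find_interior_equilibria,
    hysteresis_sweep,
    intrinsic_growth_rate,
    phase_diagram,
)


class TestInteriorEquilibria:
    def test_fitted_parameter_set_has_saddle_and_stable_pair(self, fitted_fbs5):
        eqs = find_interior_equilibria(fitted_fbs5)
        assert len(eqs) == 2
        lo, hi = eqs
        assert lo.y_star == pytest.approx(0.235, abs=0.005)
        assert hi.y_star == pytest.approx(0.784, abs=0.005)
        assert not lo.is_stable  # composition-unstable (a planar saddle)
        assert hi.is_stable
        # Y* from the C equation equals Y* from the D equation at a root
        for e in eqs:
            r_D = intrinsic_growth_rate(e.y_star, fitted_fbs5, "D")
            assert e.Y_star == pytest.approx(
                fitted_fbs5.K * (1 - fitted_fbs5.delta_D / r_D), rel=1e-6
            )

    def test_no_interior_root_without_frequency_dependence(self):
        p = ModelParams(beta=0.0, sigma=1.0, kappa=0.2).with_(n=10)
        assert find_interior_equilibria(p) == []

    def test_proportional_growth_rates_give_at_most_one_root(self):
        # r_C = A r_D exactly: kappa=0, alpha_C = A alpha_D, same sigmoid argument
        rng = np.random.default_rng(11)
        for _ in range(50):
            A = rng.uniform(0.5, 2.0)
            p = ModelParams(
                alpha_C=A, alpha_D=1.0, delta_C=0.1, delta_D=0.1, kappa=0.0,
                beta=rng.uniform(0.1, 8.0), sigma=rng.uniform(0.0, 4.0),
            ).with_(n_C=1e7, n_D=1e7)  # N_C ~= N_D: same sigmoid argument
            assert len(find_interior_equilibria(p)) <= 1

    def test_root_count_never_exceeds_two_for_sigmoidal_family(self):
        rng = np.random.default_rng(7)
        for _ in range(1500):
            alpha = 1.0
            p = ModelParams(
                alpha_C=alpha, alpha_D=alpha, delta_C=0.1, delta_D=0.1,
                kappa=rng.uniform(0.0, alpha), beta=rng.uniform(0.0, 10.0),
                sigma=rng.uniform(0.0, 10.0),
            ).with_(n=rng.uniform(2.0, 50.0))
            roots = [e for e in find_interior_equilibria(p) if e.stability != "degenerate"]
            assert len(roots) <= 2

    def test_two_roots_have_mixed_stability(self):
        rng = np.random.default_rng(23)
        seen_pairs = 0
        for _ in range(400):
            p = ModelParams(
                delta_C=0.1, delta_D=0.1, kappa=rng.uniform(0.05, 0.6),
                beta=rng.uniform(2.0, 8.0), sigma=rng.uniform(0.0, 2.0),
            ).with_(n=rng.uniform(3.0, 40.0))
            if p.beta <= p.sigma:
                continue
            eqs = [e for e in find_interior_equilibria(p) if e.stability != "degenerate"]
            if len(eqs) == 2:
                seen_pairs += 1
                stabilities = {e.is_stable for e in eqs}
                assert stabilities == {True, False}
        assert seen_pairs > 20  # the regime genuinely exercises the property

    def test_total_population_largest_in_all_C_state(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            p = ModelParams(
                delta_C=0.08, delta_D=0.08, kappa=rng.uniform(0.0, 0.5),
                beta=rng.uniform(0.0, 8.0), sigma=rng.uniform(0.0, 4.0),
            ).with_(n=rng.uniform(2.0, 30.0))
            bs = boundary_states(p)
            if "all_C" not in bs:
                continue
            for e in find_interior_equilibria(p):
                if e.stability != "degenerate":
                    assert bs["all_C"].Y_star >= e.Y_star - 1e-6

    def test_monotone_derivative_gap_implies_single_root(self):
        # when delta_D r_C' > delta_C r_D' everywhere the condition is monotone
        rng = np.random.default_rng(31)
        checked = 0
        ys = np.linspace(1e-4, 1 - 1e-4, 512)
        for _ in range(200):
            p = ModelParams(
                delta_C=0.1, delta_D=0.1, kappa=rng.uniform(0.0, 0.6),
                beta=rng.uniform(0.0, 8.0), sigma=rng.uniform(0.0, 4.0),
            ).with_(n=rng.uniform(2.0, 40.0))
            h = 1e-6
            dC = (intrinsic_growth_rate(ys + h, p, "C") - intrinsic_growth_rate(ys - h, p, "C")) / (2 * h)
            dD = (intrinsic_growth_rate(ys + h, p, "D") - intrinsic_growth_rate(ys - h, p, "D")) / (2 * h)
            if np.all(p.delta_D * dC > p.delta_C * dD):
                checked += 1
                assert len(find_interior_equilibria(p)) <= 1
        assert checked > 10


class TestBoundaryAndClassification:
    def test_producer_dominance_example(self, fig1_base):
        p = fig1_base.with_(sigma=2.0, beta=2.0, n=5)
        bs = boundary_states(p)
        assert bs["all_C"].stability == "stable"
        assert bs["all_D"].stability != "stable"
        assert classify_dynamics(p) == "C_dominance"

    @pytest.mark.parametrize(
        "sigma,beta,n,expected",
        [
            (2.0, 2.0, 5, "C_dominance"),
            (1.0, 0.25, 5, "D_dominance"),
            (1.5, 1.0, 10, "bistability"),
            (0.5, 4.0, 10, "coexistence"),
        ],
    )
    def test_reference_phase_points(self, fig1_base, sigma, beta, n, expected):
        assert classify_dynamics(fig1_base.with_(sigma=sigma, beta=beta, n=n)) == expected

    def test_nonviable_types_give_extinction(self):
        p = ModelParams(alpha_C=0.5, alpha_D=0.5, delta_C=0.6, delta_D=0.6,
                        kappa=0.2, beta=0.5, sigma=2.0).with_(n=5)
        # r_C(1) < delta and alpha_D < delta -> nothing survives
        assert intrinsic_growth_rate(1.0, p, "C") < p.delta_C
        assert classify_dynamics(p) == "extinction"
        assert boundary_states(p)["extinction"].stability == "stable"

    def test_exorbitant_cost_leaves_all_D(self):
        p = ModelParams(kappa=5.0, beta=2.0, sigma=1.0, delta_C=0.1, delta_D=0.1).with_(n=5)
        bs = boundary_states(p)
        assert "all_C" not in bs  # producers not viable on their own
        assert bs["all_D"].stability == "stable"

    def test_stability_labels_agree_with_long_time_integration(self):
        """Jacobian-based labels match the attractor reached by the flow."""
        from pggdyn import integrate_ode

        rng = np.random.default_rng(42)
        checked = 0
        while checked < 25:
            p = ModelParams(
                delta_C=0.1, delta_D=0.1, kappa=rng.uniform(0.05, 0.6),
                beta=rng.uniform(0.5, 8.0), sigma=rng.uniform(0.0, 4.0),
                K=1000.0,
            ).with_(n=rng.uniform(2.0, 40.0))
            stable = [e for e in find_interior_equilibria(p) if e.is_stable]
            if not stable:
                continue
            eq = stable[0]
            init = (eq.x_C * 1.05, eq.x_D * 0.95)
            traj = integrate_ode(p, init, 2000.0)
            assert traj.fraction_C[-1] == pytest.approx(eq.y_star, abs=0.02)
            checked += 1


class TestPhaseDiagram:
    def test_larger_neighborhoods_favor_defectors(self, fig1_base):
        betas = np.linspace(0.0, 4.0, 9)
        sigmas = np.linspace(0.0, 3.0, 7)
        small = phase_diagram(betas, sigmas, fig1_base.with_(n=5))
        large = phase_diagram(betas, sigmas, fig1_base.with_(n=10))
        c_small = (small.classes == "C_dominance").sum()
        c_large = (large.classes == "C_dominance").sum()
        assert c_large < c_small
        # raising n never converts D_dominance into C_dominance
        flipped = (small.classes == "D_dominance") & (large.classes == "C_dominance")
        assert not flipped.any()

    def test_beta_zero_column_is_defector_dominated(self, fig1_base):
        report = phase_diagram([0.0], np.linspace(0, 3, 5), fig1_base)
        assert set(report.classes.ravel()) == {"D_dominance"}

    def test_single_point_grid_matches_classifier(self, fig1_base):
        p = fig1_base.with_(sigma=2.0, beta=2.0, n=5)
        report = phase_diagram([2.0], [2.0], fig1_base.with_(n=5))
        assert report.classes[0, 0] == classify_dynamics(p)
        assert report.to_frame().shape == (1, 3)


class TestBifurcations:
    def test_saddle_node_in_n_for_strong_frequency_dependence(self):
        p = ModelParams(delta_C=0.1, delta_D=0.1, kappa=0.5, K=1000.0,
                        sigma=2.0, beta=5.0)
        diagram = bifurcation_sweep(p, "n", np.arange(8.0, 41.0, 1.0))
        kinds = {e.kind for e in diagram.events}
        assert "saddle_node" in kinds
        # after the fold no interior equilibria remain
        assert len(diagram.branches[-1]) == 0

    def test_transcritical_pattern_for_weak_frequency_dependence(self):
        p = ModelParams(delta_C=0.1, delta_D=0.1, kappa=0.5, K=1000.0,
                        sigma=3.0, beta=2.0)
        values = np.arange(2.0, 26.0, 1.0)
        diagram = bifurcation_sweep(p, "n", values)
        kinds = [e.kind for e in diagram.events]
        assert "transcritical" in kinds
        assert "saddle_node" not in kinds
        # inside the window: alternative stable monomorphic states
        mid = len(values) // 2
        assert diagram.boundary[mid]["all_C"] == "stable"
        assert diagram.boundary[mid]["all_D"] == "stable"

    def test_no_events_without_frequency_dependence(self):
        p = ModelParams(beta=0.0, sigma=1.0, kappa=0.2, delta_C=0.1, delta_D=0.1)
        diagram = bifurcation_sweep(p, "n", np.arange(2.0, 30.0, 2.0))
        assert diagram.events == []
        assert all(len(b) == 0 for b in diagram.branches)

    def test_beta_as_control_parameter(self):
        p = ModelParams(delta_C=0.1, delta_D=0.1, kappa=0.5, K=1000.0, sigma=2.0).with_(n=15)
        diagram = bifurcation_sweep(p, "beta", np.linspace(0.0, 8.0, 33))
        assert len(diagram.events) >= 1


class TestHysteresis:
    def test_bistable_window_produces_direction_dependent_branches(self):
        p = ModelParams(delta_C=0.1, delta_D=0.1, kappa=0.5, K=1000.0,
                        sigma=3.0, beta=2.0)
        sweep = hysteresis_sweep(p, "n", np.arange(2.0, 25.0, 2.0), perturbation=1.0)
        fwd = sweep[sweep.direction == "forward"].set_index("value")["y_final"]
        bwd = sweep[sweep.direction == "backward"].set_index("value")["y_final"]
        gap = (fwd - bwd).abs()
        assert (gap > 0.5).any()  # branches disagree inside the window
        assert gap.loc[gap.index.min()] < 0.05 or gap.loc[gap.index.max()] < 0.05

    def test_monostable_regime_has_identical_branches(self, fig1_base):
        p = fig1_base.with_(sigma=2.0, beta=2.0, n=5)  # producer dominance everywhere
        sweep = hysteresis_sweep(p, "beta", np.array([1.5, 2.0, 2.5]), perturbation=1.0, t_end=5000.0)
        fwd = sweep[sweep.direction == "forward"].set_index("value")["y_final"]
        bwd = sweep[sweep.direction == "backward"].set_index("value")["y_final"]
        assert np.allclose(fwd.sort_index(), bwd.sort_index(), atol=0.01)

    def test_zero_perturbation_keeps_monomorphic_state_absorbed(self):
        p = ModelParams(delta_C=0.1, delta_D=0.1, kappa=0.5, K=1000.0,
                        sigma=3.0, beta=2.0)
        sweep = hysteresis_sweep(p, "n", np.array([20.0, 22.0, 24.0]), perturbation=0.0)
        fwd = sweep[sweep.direction == "forward"]
        # starts all-D and, lacking reseeding, can never gain cooperators
        assert (fwd["y_final"] < 1e-6).all()
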