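"""Compartment simulator, renderer and assay generators."""

import numpy as np
import pytest

from spheroquant.dose import SurvivalParams, TreatmentSpec
from spheroquant.growth import DAY_GRID, GrowthCurve, classify_regime
from spheroquant.imaging import quantify_frame
from spheroquant.render import (
    RenderConfig,
    generate_timelapse,
    render_frame,
    write_timelapse_tiff,
)
from spheroquant.simulate import (
    CANONICAL_REGIMES,
    CANONICAL_SCENARIOS,
    PopulationState,
    SimConfig,
    generate_clonogenic_dataset,
    generate_viability_dataset,
    simulate,
    trajectory_table,
)


def daily_diameters(states):
    tab = trajectory_table(states)
    return tab[tab.time_h % 24 == 0].diameter_um.to_numpy()


def as_curve(diameters):
    return GrowthCurve(
        day=DAY_GRID, mean=diameters, sem=np.zeros(22),
        n_repeats=np.full(22, 3, int),
    )


class TestSimulator:
    def test_control_monotone_growth_and_determinism(self):
        cfg = SimConfig(seed=11)
        states = simulate(cfg)
        d = daily_diameters(states)
        assert np.all(np.diff(d) > 0)
        assert d[-1] > d[0]
        d2 = daily_diameters(simulate(SimConfig(seed=11)))
        assert np.array_equal(d, d2)

    def test_null_thermal_treatment_equals_control(self):
        # a heat dose with S_HT = 1 (a = b = 0) must leave the trajectory
        # identical to control, loosening included
        pars = SurvivalParams(alpha0=0.55, beta=0.036)
        cfg = SimConfig(survival_params=pars)
        control = trajectory_table(simulate(cfg, TreatmentSpec()))
        heated = trajectory_table(simulate(cfg, TreatmentSpec.heat(500.0)))
        assert np.allclose(control.diameter_um, heated.diameter_um)
        assert np.allclose(control.rho, heated.rho)

    def test_mass_balance_every_step(self):
        # bookkeeping oracle: attached + shed must equal the initial count
        # plus cumulative births at every step — cells are reclassified,
        # never destroyed
        for name, tr in CANONICAL_SCENARIOS.items():
            states = simulate(SimConfig(), tr)
            n0 = states[0].total_attached + states[0].Shed
            for s in states:
                lhs = s.total_attached + s.Shed
                rhs = n0 + s.cum_births
                assert lhs == pytest.approx(rhs, rel=1e-9), (name, s.t)

    def test_initial_diameter_honoured(self):
        for dia in (300.0, 550.0):
            s0 = simulate(SimConfig(initial_diameter=dia))[0]
            assert s0.diameter_um == pytest.approx(dia, rel=1e-9)

    def test_ht_kill_is_position_independent(self):
        # HT removes the same fraction from P, Q and C alike
        cfg = SimConfig(initial_diameter=550.0)
        control0 = simulate(cfg)[0]
        heated0 = simulate(cfg, TreatmentSpec.heat(120.0))[0]
        s_ht = np.exp(-cfg.survival_params.a_thermal * 120.0)
        assert heated0.Q == pytest.approx(control0.Q * s_ht, rel=1e-9)
        assert heated0.C == pytest.approx(control0.C * s_ht, rel=1e-9)
        assert heated0.A == pytest.approx(
            (control0.P + control0.Q + control0.C) * (1 - s_ht), rel=1e-9
        )

    def test_rt_kill_targets_proliferating_cells_only(self):
        cfg = SimConfig()
        control0 = simulate(cfg)[0]
        irr0 = simulate(cfg, TreatmentSpec.radiation(10.0))[0]
        # quiescent pool untouched at t = 0; doomed cells still attached
        assert irr0.Q == pytest.approx(control0.Q, rel=1e-9)
        assert irr0.A == 0.0
        assert irr0.p_doomed > 0
        assert irr0.diameter_um == pytest.approx(control0.diameter_um, rel=1e-9)

    @pytest.mark.parametrize("scenario", list(CANONICAL_SCENARIOS))
    def test_canonical_regimes_across_seeds(self, scenario):
        # ground-truth dynamics are deterministic; seeds vary the renderer
        # stream only, so a spread of seeds must agree on the regime
        tr = CANONICAL_SCENARIOS[scenario]
        for seed in range(0, 20):
            d = daily_diameters(simulate(SimConfig(seed=seed), tr))
            assert classify_regime(as_curve(d)) == CANONICAL_REGIMES[scenario]

    def test_ht_transient_swelling_above_day0(self):
        d = daily_diameters(simulate(SimConfig(), TreatmentSpec.heat(240.0)))
        assert d.max() > d[0]  # loosening-driven transient increase
        assert d.min() < d[0]  # later shrinkage below the starting size
        # regrowth once survivors repopulate
        assert d[-1] > d.min()

    def test_rt_never_swells(self):
        d = daily_diameters(simulate(SimConfig(), TreatmentSpec.radiation(10.0)))
        assert d.max() == pytest.approx(d[0])

    def test_ht_dead_cells_peak_earlier_than_rt(self):
        # matched total effect: thermal-only vs radiation-only at the same E
        from spheroquant.dose import isoeffect_combinations, treatment_effect

        cfg = SimConfig()
        pars = cfg.survival_params
        e10 = treatment_effect(TreatmentSpec.radiation(10.0), pars)
        (_, h_iso), = isoeffect_combinations(e10, pars, [0.0])
        ht = trajectory_table(simulate(cfg, TreatmentSpec.heat(h_iso)))
        rt = trajectory_table(simulate(cfg, TreatmentSpec.radiation(10.0)))
        t_ht = ht.day[ht.dead_attached_fraction.idxmax()]
        t_rt = rt.day[rt.dead_attached_fraction.idxmax()]
        assert t_rt - t_ht >= 2.0

    def test_reoxygenation_boost_accelerates_regrowth(self):
        tr = TreatmentSpec.heat(160.0)
        fast = daily_diameters(simulate(SimConfig(), tr))
        slow = daily_diameters(
            simulate(SimConfig(reoxygenation_enabled=False), tr)
        )
        assert fast[-1] >= slow[-1]

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(loosening_factor=1.2)
        with pytest.raises(ValueError):
            SimConfig(growth_rate=-0.1)


class TestRenderer:
    def test_no_dead_cells_pi_at_noise_floor(self):
        state = PopulationState(t=0.0, P=3000.0, Q=1000.0, C=0.0, A=0.0,
                                Shed=0.0, rho=3.4e-4)
        rcfg = RenderConfig(image_size=512, noise_sigma=0.01)
        rf = render_frame(state, rcfg, np.random.default_rng(0))
        assert rf.frame.pi.max() <= 5 * 0.01 + 1e-9

    def test_corona_intensity_monotone_in_shed(self):
        base = dict(t=96.0, P=2000.0, Q=500.0, C=0.0, A=500.0, rho=3.4e-4,
                    a_ht=500.0)
        rcfg = RenderConfig(image_size=512, noise_sigma=0.0)
        lo = render_frame(PopulationState(Shed=200.0, **base), rcfg,
                          np.random.default_rng(1))
        hi = render_frame(PopulationState(Shed=2000.0, **base), rcfg,
                          np.random.default_rng(1))
        r_px = lo.state.radius_um
        n = rcfg.image_size
        yy, xx = np.mgrid[0:n, 0:n]
        dist = np.hypot(yy - (n - 1) / 2, xx - (n - 1) / 2)
        ring = (dist >= r_px + rcfg.corona_gap_px) & (
            dist <= r_px + rcfg.corona_gap_px + rcfg.corona_width_px
        )
        assert hi.frame.pi[ring].mean() > lo.frame.pi[ring].mean()
        # interior PI identical: same attached composition
        inside = dist <= r_px - 2
        assert np.allclose(hi.frame.pi[inside], lo.frame.pi[inside])

    def test_ht_staining_centre_weighted_rt_edge_weighted(self):
        common = dict(t=48.0, P=1000.0, Q=500.0, C=0.0, Shed=0.0, rho=3.4e-4)
        rcfg = RenderConfig(image_size=512, noise_sigma=0.0)
        ht = render_frame(
            PopulationState(A=1500.0, a_ht=1500.0, **common), rcfg,
            np.random.default_rng(2),
        )
        rt = render_frame(
            PopulationState(A=1500.0, a_rt=1500.0, **common), rcfg,
            np.random.default_rng(2),
        )
        n = rcfg.image_size
        yy, xx = np.mgrid[0:n, 0:n]
        dist = np.hypot(yy - (n - 1) / 2, xx - (n - 1) / 2)
        r_px = ht.state.radius_um
        centre = dist <= 0.3 * r_px
        edge = (dist >= 0.7 * r_px) & (dist <= 0.95 * r_px)
        assert ht.frame.pi[centre].mean() > ht.frame.pi[edge].mean()
        assert rt.frame.pi[edge].mean() > rt.frame.pi[centre].mean()

    def test_canvas_too_small_rejected(self):
        state = PopulationState(t=0.0, P=5e5, Q=0.0, C=0.0, A=0.0, Shed=0.0,
                                rho=3.4e-4)
        with pytest.raises(ValueError, match="image_size"):
            render_frame(state, RenderConfig(image_size=64))

    def test_roundtrip_against_measurement(self):
        state = simulate(SimConfig())[30]
        rf = render_frame(state, RenderConfig(), np.random.default_rng(3))
        metrics, _, _ = quantify_frame(rf.frame)
        assert metrics.mean_diameter == pytest.approx(rf.diameter_um, rel=0.02)


class TestTimelapse:
    def test_ground_truth_identical_across_seeds(self):
        tls = [
            generate_timelapse(
                SimConfig(seed=s), TreatmentSpec.heat(80.0),
                RenderConfig(image_size=512), frame_interval_h=168.0,
            )
            for s in (1, 2, 3)
        ]
        ref = tls[0].ground_truth.diameter_um
        for tl in tls[1:]:
            assert np.allclose(tl.ground_truth.diameter_um, ref)
        # distinct noise realisations
        a = tls[0].frames[0].frame.phase
        b = tls[1].frames[0].frame.phase
        assert not np.allclose(a, b)

    def test_daily_frames_subsample_ground_truth(self):
        tl = generate_timelapse(
            SimConfig(seed=4), None,
            RenderConfig(image_size=512, pixel_size=2.0),
            frame_interval_h=24.0,
        )
        gt = tl.ground_truth
        daily = gt[gt.time_h % 24 == 0].diameter_um.to_numpy()
        frame_d = np.array([rf.diameter_um for rf in tl.frames])
        assert np.array_equal(frame_d, daily)
        assert len(tl.frames) == 22

    def test_bad_cadence_rejected(self):
        with pytest.raises(ValueError, match="multiple"):
            generate_timelapse(SimConfig(), frame_interval_h=10.0)

    def test_tiff_roundtrip(self, tmp_path):
        import tifffile

        tl = generate_timelapse(
            SimConfig(seed=9), None,
            RenderConfig(image_size=256, pixel_size=4.0),
            frame_interval_h=252.0,
        )
        path = tmp_path / "tl.tiff"
        write_timelapse_tiff(tl, path)
        stack = tifffile.imread(path)
        assert stack.shape[0] == 2 * len(tl.frames)
        assert np.allclose(stack[0], tl.frames[0].frame.phase, atol=1e-6)


class TestAssayGenerators:
    def test_colony_count_mean_property(self):
        # untreated, full plating efficiency: expected colonies = n_plated
        pars = SurvivalParams()  # S = 1 everywhere
        recs = generate_clonogenic_dataset(
            pars, [TreatmentSpec()], n_plated=200, plating_efficiency=1.0,
            n_reps=1000, seed=42,
        )
        counts = np.array([r.n_colonies for r in recs])
        se = np.sqrt(200 / 1000)
        assert abs(counts.mean() - 200) <= max(3 * se, 1e-9)
        assert counts.max() <= 200

    def test_colony_counting_noise_near_poisson_when_sparse(self):
        # sparse regime: variance ~ mean, the Poisson counting limit
        pars = SurvivalParams(alpha0=0.3, beta=0.03)
        recs = generate_clonogenic_dataset(
            pars, [TreatmentSpec.radiation(5.0)], n_plated=10**5,
            plating_efficiency=0.5, n_reps=600, seed=13,
        )
        counts = np.array([r.n_colonies for r in recs])
        ratio = counts.var(ddof=1) / counts.mean()
        assert 0.8 <= ratio <= 1.2

    def test_lethal_treatment_yields_zero_colonies(self):
        pars = SurvivalParams(alpha0=5.0)
        recs = generate_clonogenic_dataset(
            pars, [TreatmentSpec.radiation(20.0)], n_plated=1000,
            n_reps=20, seed=0,
        )
        assert all(r.n_colonies == 0 for r in recs)

    def test_seeded_reproducibility(self):
        pars = SurvivalParams(alpha0=0.3, beta=0.03)
        kw = dict(treatments=[TreatmentSpec.radiation(2.0)], n_plated=1000,
                  n_reps=5)
        a = generate_clonogenic_dataset(pars, seed=5, **kw)
        b = generate_clonogenic_dataset(pars, seed=5, **kw)
        assert [r.n_colonies for r in a] == [r.n_colonies for r in b]

    def test_viability_self_ratio(self):
        s = simulate(SimConfig())[24]  # day 4 state
        df = generate_viability_dataset({"same": s}, s, noise_cv=0.0)
        assert np.allclose(df.relative_viability, 1.0)

    def test_viability_half_live_cells(self):
        cfg = SimConfig()
        control = simulate(cfg)[0]
        halved = PopulationState(
            t=0.0, P=control.P / 2, Q=control.Q / 2, C=control.C,
            A=0.0, Shed=0.0, rho=cfg.packing_density,
        )
        df = generate_viability_dataset({"half": halved}, control, noise_cv=0.0)
        assert np.allclose(df.relative_viability, 0.5)

    def test_viability_noise_cv_calibrated(self):
        s = simulate(SimConfig())[0]
        df = generate_viability_dataset(
            {"x": s}, s, noise_cv=0.1, n_reps=1000, seed=8
        )
        vals = df.relative_viability.to_numpy()
        cv = vals.std(ddof=1) / vals.mean()
        assert 0.08 <= cv <= 0.12

    def test_missing_control_rejected(self):
        dead = PopulationState(t=0.0, P=0.0, Q=0.0, C=0.0, A=10.0,
                               Shed=0.0, rho=3.4e-4)
        with pytest.raises(ValueError, match="control"):
            generate_viability_dataset({}, dead)
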