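"""Mass-balance simulator: flows, steady-state oracle, dynamics, accounting."""

import dataclasses

import numpy as np
import pytest

from iaqsim.building import FilterSpec, Schedule, default_apartment, filter_schedule
from iaqsim.iaq_sim import (
    build_flows,
    mass_budget,
    simulate,
    steady_state,
)
from iaqsim.synth_env import AERSeries, AmbientSeries, HOURS_PER_YEAR


def constant_series(pm25=123.0, aer=1.5):
    return (
        AmbientSeries(pm25=np.full(HOURS_PER_YEAR, pm25)),
        AERSeries(aer=np.full(HOURS_PER_YEAR, aer)),
    )


def bare_single_zone(**overrides):
    """75 m³ single zone, no fans/sources/filter unless overridden."""
    apt = default_apartment().single_zone()
    base = dict(fans=(), sources=())
    base.update(overrides)
    return dataclasses.replace(apt, **base)


class TestFlows:
    def test_envelope_infiltration_no_fans(self):
        apt = bare_single_zone()
        flows = build_flows(apt, np.full(48, 1.5))
        np.testing.assert_allclose(flows.q_inf, 1.5 * 75.0)
        np.testing.assert_allclose(flows.q_exf, 1.5 * 75.0)

    def test_fan_induces_matching_makeup(self):
        apt = default_apartment()
        flows = build_flows(apt, np.full(48, 1.5))
        h = 17  # kitchen fan at full duty while cooking 17:00-18:00
        assert flows.q_fan[h].sum() == pytest.approx(170.0)
        assert flows.q_inf[h].sum() == pytest.approx(1.5 * 75.0 + 170.0)
        kitchen = apt.zone_names.index("kitchen")
        assert flows.q_fan[h, kitchen] == pytest.approx(170.0)
        # make-up air enters through the non-fan zones
        assert flows.q_inf[h, kitchen] == pytest.approx(1.5 * apt.zones[kitchen].volume)

    def test_air_mass_balance_every_zone_and_hour(self, env_seed1):
        apt = default_apartment()
        _, aer = env_seed1
        flows = build_flows(apt, aer.aer[:240])
        assert np.abs(flows.balance_residual()).max() < 1e-9 * 75.0

    def test_negative_aer_rejected(self):
        with pytest.raises(ValueError):
            build_flows(default_apartment(), np.array([1.0, -0.5]))


class TestSteadyStateOracle:
    def test_infiltration_only_closed_form(self):
        """Single zone with a=1.5/h, k=0.19/h, C_out=123: a·C_out/(a+k)."""
        c = steady_state(bare_single_zone(), 123.0, 1.5)
        assert c[0] == pytest.approx(1.5 * 123.0 / (1.5 + 0.19), rel=1e-12)
        assert round(c[0], 1) == 109.2

    def test_hepa_closed_form(self):
        apt = bare_single_zone(filter=FilterSpec(efficiency=0.99))
        c = steady_state(apt, 123.0, 1.5, filter_on=True)
        expected = 1.5 * 123.0 / (1.5 + 0.19 + 0.99 * 339.6 / 75.0)
        assert c[0] == pytest.approx(expected, rel=1e-12)
        assert round(c[0], 1) == 29.9

    def test_source_closed_form(self):
        src = dataclasses.replace(
            default_apartment().sources[0], zone="home", schedule=Schedule.always_on()
        )
        apt = bare_single_zone(sources=(src,))
        c = steady_state(apt, 0.0, 1.5, sources_on=True)
        # S = 0.14 mg/min = 8400 µg/h; (S/V)/(a + k)
        assert c[0] == pytest.approx(8400.0 / 75.0 / 1.69, rel=1e-12)
        assert round(c[0], 1) == 66.3

    def test_zero_forcing_gives_zero(self):
        assert steady_state(bare_single_zone(), 0.0, 1.5)[0] == pytest.approx(0.0)

    def test_singular_system_rejected(self):
        src = dataclasses.replace(
            default_apartment().sources[0], zone="home", schedule=Schedule.always_on()
        )
        apt = bare_single_zone(sources=(src,), deposition_rate_per_h=0.0)
        with pytest.raises(ValueError, match="singular"):
            steady_state(apt, 0.0, 0.0, sources_on=True)

    def test_strong_mixing_approaches_single_zone(self):
        """With doorway mixing → ∞ all zones converge to the volume-weighted
        single-zone concentration."""
        apt = dataclasses.replace(default_apartment(), interzonal_flow_m3h=1e6)
        c = steady_state(apt, 123.0, 1.5)
        single = steady_state(apt.single_zone(), 123.0, 1.5)[0]
        np.testing.assert_allclose(c, single, rtol=1e-3)


class TestSimulateDynamics:
    def test_matches_oracle_under_constant_forcing(self):
        ambient, aer = constant_series()
        for apt, kwargs in [
            (bare_single_zone(), {}),
            (bare_single_zone(filter=FilterSpec(efficiency=0.99)), {"filter_on": True}),
            (bare_single_zone(filter=FilterSpec(efficiency=0.65)), {"filter_on": True}),
        ]:
            field = simulate(apt, ambient, aer, n_hours=60)
            expected = steady_state(apt, 123.0, 1.5, **kwargs)[0]
            assert field.values[-1, 0] == pytest.approx(expected, rel=1e-3)

    def test_multizone_matches_oracle_under_constant_forcing(self):
        ambient, aer = constant_series()
        apt = dataclasses.replace(default_apartment(), fans=(), sources=())
        field = simulate(apt, ambient, aer, n_hours=60)
        expected = steady_state(apt, 123.0, 1.5)
        np.testing.assert_allclose(field.values[-1], expected, rtol=1e-3)

    def test_pure_loss_decays_monotonically(self):
        """With outdoor air at trace level and no sources, concentrations can
        only decay from the polluted initial day."""
        pm25 = np.full(HOURS_PER_YEAR, 1e-6)
        pm25[:24] = 200.0
        ambient = AmbientSeries(pm25=pm25)
        aer = AERSeries(aer=np.full(HOURS_PER_YEAR, 1.5))
        field = simulate(bare_single_zone(), ambient, aer, n_hours=96)
        tail = field.values[24:, 0]
        # strictly decaying until it reaches the trace-ambient floor
        assert np.all(np.diff(tail) < 1e-6)
        assert tail[-1] < 1e-3

    def test_nonnegative_everywhere(self, env_seed1):
        ambient, aer = env_seed1
        apt = dataclasses.replace(
            default_apartment(), filter=FilterSpec(efficiency=0.99)
        )
        field = simulate(apt, ambient, aer, n_hours=480)
        assert np.all(field.values >= 0)
        assert np.all(np.isfinite(field.values))

    def test_dt_must_divide_hour(self, env_seed1):
        ambient, aer = env_seed1
        with pytest.raises(ValueError):
            simulate(bare_single_zone(), ambient, aer, dt_minutes=7, n_hours=24)

    def test_filter_monotonicity(self, env_seed1):
        """Pointwise: more filtration (higher efficiency or longer use hours)
        never increases any concentration under the same forcing."""
        ambient, aer = env_seed1
        base = default_apartment().single_zone()
        runs = {}
        for eff_label, eff in [("none", None), ("low", 0.30), ("mid", 0.65), ("hepa", 0.99)]:
            filt = None if eff is None else FilterSpec(efficiency=eff)
            apt = dataclasses.replace(base, filter=filt)
            runs[eff_label] = simulate(apt, ambient, aer, n_hours=240).values
        tol = 1e-9
        assert np.all(runs["low"] <= runs["none"] + tol)
        assert np.all(runs["mid"] <= runs["low"] + tol)
        assert np.all(runs["hepa"] <= runs["mid"] + tol)

        hours = {}
        for sched in ("8h", "15h", "24h"):
            apt = dataclasses.replace(
                base, filter=FilterSpec(efficiency=0.99, schedule=filter_schedule(sched))
            )
            hours[sched] = simulate(apt, ambient, aer, n_hours=240).values
        assert np.all(hours["15h"] <= hours["8h"] + tol)
        assert np.all(hours["24h"] <= hours["15h"] + tol)

    def test_well_mixed_consistency(self, env_seed1):
        """Multi-zone with huge doorway mixing reproduces single-zone hourly
        values within 1%."""
        ambient, aer = env_seed1
        apt = default_apartment()
        big = dataclasses.replace(apt, interzonal_flow_m3h=1e4)
        vw = simulate(big, ambient, aer, n_hours=240).volume_weighted_mean(big.volumes)
        single = simulate(apt.single_zone(), ambient, aer, n_hours=240).values[:, 0]
        assert np.max(np.abs(vw - single) / single) < 0.01

    def test_concentration_csv_round_trip(self, env_seed1, tmp_path):
        import pandas as pd

        ambient, aer = env_seed1
        field = simulate(default_apartment(), ambient, aer, n_hours=48)
        path = tmp_path / "field.csv"
        field.to_csv(path)
        df = pd.read_csv(path)
        assert set(df["zone"]) == set(field.zone_names)
        pivot = df.pivot(index="hour_index", columns="zone", values="pm25_ugm3")
        np.testing.assert_allclose(
            pivot[list(field.zone_names)].to_numpy(), field.values, rtol=1e-10
        )


class TestMassAccounting:
    def test_budget_closes_with_all_terms(self, env_seed1):
        ambient, aer = env_seed1
        apt = dataclasses.replace(
            default_apartment(), filter=FilterSpec(efficiency=0.99)
        )
        field = simulate(apt, ambient, aer, n_hours=720)
        budget = mass_budget(field, apt, ambient, aer)
        assert abs(budget["relative_imbalance"]) < 1e-9

    def test_emitted_mass_fully_accounted_over_year(self):
        """Source-only year with near-zero concentrations at both ends:
        emitted mass equals deposited + exfiltrated + filtered within 0.5%."""
        pm25 = np.full(HOURS_PER_YEAR, 1e-9)
        ambient = AmbientSeries(pm25=pm25)
        aer = AERSeries(aer=np.full(HOURS_PER_YEAR, 1.5))
        apt = default_apartment().single_zone()
        apt = dataclasses.replace(apt, filter=FilterSpec(efficiency=0.65))
        field = simulate(apt, ambient, aer)
        budget = mass_budget(field, apt, ambient, aer)
        recovered = (
            budget["deposited_ug"] + budget["exfiltrated_ug"] + budget["filtered_ug"]
        )
        emitted = budget["emitted_ug"]
        assert emitted == pytest.approx(0.14 * 120 * 365 * 1e3, rel=1e-9)
        assert recovered == pytest.approx(emitted, rel=0.005)
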