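import numpy as np
import pytest

from rstarcomp import rct_simulator as sim

from conftest import two_species_scenario


class TestScenarioValidation:
    def test_bad_pulse_fraction(self):
        with pytest.raises(ValueError):
            sim.ResourceSupply("N", 1.0, "pulse", pulse_fraction=1.5)

    def test_bad_kind(self):
        with pytest.raises(ValueError):
            sim.ResourceSupply("N", 1.0, "weird")

    def test_nonpositive_kinetics(self):
        with pytest.raises(ValueError):
            sim.SpeciesParams("A", {"R": (0.0, 1.0)})

    def test_mismatched_pulses(self):
        sp = sim.SpeciesParams("A", {"R": (1.0, 1.0)}, {"R": 1.0})
        with pytest.raises(ValueError, match="share fraction"):
            sim.SimScenario([sp], [
                sim.ResourceSupply("R", 1.0, "pulse", pulse_fraction=0.1),
                sim.ResourceSupply("Q", 1.0, "pulse", pulse_fraction=0.2),
            ])

    def test_bad_horizon(self):
        sp = sim.SpeciesParams("A", {"R": (1.0, 1.0)})
        with pytest.raises(ValueError):
            sim.SimScenario([sp], [sim.ResourceSupply("R", 1.0, "constant")],
                            horizon=0.0)


class TestSimulate:
    def test_chemostat_steady_state_equals_r_star(self):
        # mu_max=1, Ks=1, m=D=0.1 -> R_hat = 0.1*1/(1-0.1) = 1/9
        sp = sim.SpeciesParams("A", {"R": (1.0, 1.0)}, {"R": 1.0}, b0=0.1)
        sc = sim.SimScenario([sp], [sim.ResourceSupply("R", 10.0, "chemostat",
                                                       dilution=0.1)],
                             m=0.1, horizon=1000.0)
        res = sim.simulate(sc)
        assert res.resources[-1, 0] == pytest.approx(1.0 / 9.0, abs=1e-4)

    def test_unlimited_exponential_growth(self):
        sp = sim.SpeciesParams("A", {"R": (0.7, 1.0)}, {}, b0=0.5)
        sc = sim.SimScenario([sp], [sim.ResourceSupply("R", 1e9, "constant")],
                             m=0.0, horizon=10.0)
        res = sim.simulate(sc)
        expected = 0.5 * np.exp(0.7 * res.t)
        assert np.allclose(res.biomass[:, 0], expected, rtol=1e-6)

    def test_competitive_exclusion(self):
        res = sim.simulate(two_species_scenario())  # R*: 0.056 vs 0.22
        assert res.winner == "A"
        assert res.final_relative_abundance()[0] > 0.99

    def test_nonnegative_states(self):
        res = sim.simulate(two_species_scenario(horizon=200.0))
        assert np.all(res.biomass >= 0)
        assert np.all(res.resources >= 0)

    def test_mass_balance_closed_mode(self):
        # no supply, no mortality: q*B + R conserved
        sp = sim.SpeciesParams("A", {"R": (1.0, 1.0)}, {"R": 2.0}, b0=0.1)
        sc = sim.SimScenario([sp], [sim.ResourceSupply("R", 0.0, "chemostat",
                                                       dilution=0.0, initial=5.0)],
                             m=0.0, horizon=50.0)
        res = sim.simulate(sc)
        total = 2.0 * res.biomass[:, 0] + res.resources[:, 0]
        assert np.allclose(total, total[0], rtol=1e-6)

    def test_pulse_events_logged_and_applied(self):
        sp = sim.SpeciesParams("A", {"R": (0.5, 1.0)}, {"R": 1.0}, b0=0.1)
        f = sim.MESOCOSM_PULSE_FRACTION
        sc = sim.SimScenario([sp], [sim.ResourceSupply("R", 100.0, "pulse",
                                                       pulse_fraction=f)],
                             m=0.013, horizon=28.0)
        res = sim.simulate(sc)
        assert len(res.events) == 4
        assert all(e["type"] == "pulse" for e in res.events)

    def test_pulsed_average_loss_matches_formula(self):
        # unlimited growth + weekly pulses: realized rate = mu - ln(1-f)/7 - m
        sp = sim.SpeciesParams("A", {"R": (0.5, 1e-6)}, {}, b0=1.0)
        f = sim.MESOCOSM_PULSE_FRACTION
        sc = sim.SimScenario(
            [sp],
            [sim.ResourceSupply("R", 1e9, "constant"),
             sim.ResourceSupply("D", 1e9, "pulse", pulse_fraction=f)],
            m=0.0, horizon=70.0)
        res = sim.simulate(sc)
        pulse_loss = -np.log(1 - f) / 7.0
        assert pulse_loss == pytest.approx(0.0136, abs=2e-4)  # brackets m=0.013
        assert sim.effective_loss_rate(sc) == pytest.approx(pulse_loss, abs=1e-12)
        # 9 pulses fall strictly inside (0, 70); the one at t=70 post-dates
        # the recorded final state
        expected = np.log(res.biomass[0, 0]) + 0.5 * 70.0 + 9 * np.log(1 - f)
        assert np.log(res.biomass[-1, 0]) == pytest.approx(expected, abs=1e-6)

    def test_liebig_consistency(self):
        # second resource in vast excess: dynamics equal single-resource run
        sp2 = sim.SpeciesParams("A", {"R": (1.0, 0.5), "Q": (5.0, 1e-9)},
                                {"R": 1.0, "Q": 0.0}, b0=0.1)
        sc2 = sim.SimScenario([sp2], [
            sim.ResourceSupply("R", 10.0, "chemostat", dilution=0.1),
            sim.ResourceSupply("Q", 1e9, "constant"),
        ], m=0.1, horizon=100.0)
        sp1 = sim.SpeciesParams("A", {"R": (1.0, 0.5)}, {"R": 1.0}, b0=0.1)
        sc1 = sim.SimScenario([sp1], [sim.ResourceSupply("R", 10.0, "chemostat",
                                                         dilution=0.1)],
                              m=0.1, horizon=100.0)
        r2, r1 = sim.simulate(sc2), sim.simulate(sc1)
        assert np.allclose(r2.biomass[:, 0], r1.biomass[:, 0], rtol=1e-6)


class TestEquilibriumResource:
    def test_shared_oracle_values(self):
        sp = sim.SpeciesParams("A", {"R": (1.0, 1.0)}, {"R": 1.0})
        sc = sim.SimScenario([sp], [sim.ResourceSupply("R", 10.0, "chemostat",
                                                       dilution=0.013)],
                             m=0.013, horizon=1.0)
        assert sim.equilibrium_resource(sc, sp)["R"] == pytest.approx(
            0.013171225937, abs=1e-9)

    def test_zero_loss(self):
        sp = sim.SpeciesParams("A", {"R": (1.0, 1.0)}, {"R": 1.0})
        sc = sim.SimScenario([sp], [sim.ResourceSupply("R", 10.0, "chemostat")],
                             m=0.0, horizon=1.0)
        assert sim.equilibrium_resource(sc, sp)["R"] == 0.0

    def test_simulated_equilibrium_agrees(self):
        sp = sim.SpeciesParams("A", {"R": (1.0, 2.0)}, {"R": 1.0}, b0=0.1)
        sc = sim.SimScenario([sp], [sim.ResourceSupply("R", 10.0, "chemostat",
                                                       dilution=0.05)],
                             m=0.05, horizon=2000.0)
        analytic = sim.equilibrium_resource(sc, sp)["R"]
        res = sim.simulate(sc)
        assert abs(res.resources[-1, 0] - analytic) < 1e-4

    def test_loss_exceeds_mu_max(self):
        sp = sim.SpeciesParams("A", {"R": (0.01, 1.0)})
        sc = sim.SimScenario([sp], [sim.ResourceSupply("R", 1.0, "chemostat")],
                             m=0.1, horizon=1.0)
        with pytest.raises(sim.NonViableScenarioError):
            sim.equilibrium_resource(sc, sp)


class TestTreatmentSuite:
    def test_supply_ratios(self):
        sup = sim.mesocosm_supplies("Redfield")
        assert sup["N"] / sup["P"] == pytest.approx(16.0)
        sup = sim.mesocosm_supplies("N-lim")
        assert sup["N"] == 80.0 and sup["N"] / sup["P"] == pytest.approx(8.0)
        sup = sim.mesocosm_supplies("P-lim")
        assert sup["P"] == 5.0 and sup["N"] / sup["P"] == pytest.approx(32.0)
        assert sim.mesocosm_supplies("L-lim")["light"] < \
            sim.mesocosm_supplies("Redfield")["light"]

    def test_unknown_treatment(self):
        with pytest.raises(ValueError):
            sim.mesocosm_supplies("K-lim")

    def test_missing_resource_errors(self):
        sp = sim.SpeciesParams("A", {"N": (1.0, 1.0)}, {"N": 1.0})
        sc = sim.SimScenario([sp], [sim.ResourceSupply("N", 160.0, "chemostat")],
                             horizon=1.0)
        with pytest.raises(ValueError, match="missing resource"):
            sim.run_treatment_suite(sc)

    def test_suite_keys_and_supplies(self, mesocosm_base):
        results = sim.run_treatment_suite(mesocosm_base)
        assert set(results) == {"L-lim", "N-lim", "P-lim", "Redfield"}

    def test_min_rstar_species_wins_per_treatment(self):
        # sp_n is the N specialist, sp_p the P specialist (R* gaps >= 2x)
        quotas = {"N": 1.0, "P": 0.0625}
        sp_n = sim.SpeciesParams("sp_n", {"light": (1.0, 10.0), "N": (1.0, 0.4),
                                          "P": (1.0, 0.16)}, quotas, 0.1)
        sp_p = sim.SpeciesParams("sp_p", {"light": (1.0, 10.0), "N": (1.0, 1.6),
                                          "P": (1.0, 0.04)}, quotas, 0.1)
        base = sim.SimScenario([sp_n, sp_p], [
            sim.ResourceSupply("N", 16.0, "chemostat", dilution=0.1),
            sim.ResourceSupply("P", 1.0, "chemostat", dilution=0.1),
            sim.ResourceSupply("light", 300.0, "constant"),
        ], m=0.1, horizon=600.0)
        results = sim.run_treatment_suite(base)
        assert results["N-lim"].winner == "sp_n"
        assert results["P-lim"].winner == "sp_p"
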