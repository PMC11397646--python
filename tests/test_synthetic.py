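"""Generator determinism and ground-truth round-trip recovery."""

import numpy as np
import pandas as pd
import pytest

from anomeric import (
    AnomerEquilibrium,
    AValue,
    SimulationConfig,
    ThermoConstants,
    anomeric_stabilization,
    classify_anomer,
    fit_equilibration,
    gen_equilibrium_dataset,
    gen_mutarotation_series,
    gen_nmr_observables,
    gen_torsion_profile,
    is_equilibrated,
    periodicity_score,
    scan_extrema,
)
from anomeric.synthetic import observables_from_row


class TestDeterminism:
    def test_same_seed_same_stream(self):
        c = SimulationConfig(seed=42)
        pd.testing.assert_frame_equal(gen_equilibrium_dataset(c),
                                      gen_equilibrium_dataset(c))
        s1, t1 = gen_mutarotation_series(c)
        s2, t2 = gen_mutarotation_series(c)
        assert s1 == s2 and t1 == t2
        pd.testing.assert_frame_equal(gen_nmr_observables(c, 50),
                                      gen_nmr_observables(c, 50))

    def test_different_seeds_differ(self):
        a = gen_equilibrium_dataset(SimulationConfig(seed=1))
        b = gen_equilibrium_dataset(SimulationConfig(seed=2))
        assert not a["percent_beta"].equals(b["percent_beta"])


class TestEquilibriumInversion:
    @pytest.mark.parametrize("e_an,expected_beta,tol", [
        (1.25, 50.0, 1e-6),     # E_an = A => dG_an = 0
        (1.32, 47.1, 0.1),      # reference tetrahydropyranol
        (0.125, 86.7, 0.1),     # beta-dominant imine
    ])
    def test_known_inversions(self, e_an, expected_beta, tol):
        cfg = SimulationConfig(e_an_range=(e_an - 1e-9, e_an + 1e-9))
        df = gen_equilibrium_dataset(cfg)
        assert df["percent_beta"].iloc[0] == pytest.approx(expected_beta, abs=tol)

    def test_analysis_recovers_true_e_an(self):
        """Generate populations from E_an, re-derive E_an: exact round trip."""
        cfg = SimulationConfig(seed=11, n_compounds=50)
        df = gen_equilibrium_dataset(cfg)
        constants = ThermoConstants(rt_mode="paper_rounded")
        a = AValue("OH", "cyclohexane", cfg.a_value)
        for _, row in df.iterrows():
            eq = AnomerEquilibrium(row["compound_id"], row["solvent"],
                                   row["temperature_K"],
                                   row["percent_beta"], row["percent_alpha"])
            res = anomeric_stabilization(eq, a, constants)
            assert res.e_an == pytest.approx(row["true_e_an"], abs=1e-9)

    def test_populations_within_physical_bounds(self):
        df = gen_equilibrium_dataset(SimulationConfig(seed=5, n_compounds=200,
                                                      e_an_range=(-4.0, 5.0)))
        assert ((df["percent_beta"] > 0.1) & (df["percent_beta"] < 99.9)).all()


class TestMutarotationGeneration:
    def test_noiseless_series_recovered_exactly(self):
        cfg = SimulationConfig(seed=3, noise_sigma_points=0.0)
        series, truth = gen_mutarotation_series(cfg)
        fit = fit_equilibration(series)
        if fit.equilibrated_from_start:
            assert abs(fit.beta_eq - truth["beta_eq"]) < 0.5
        else:
            assert fit.beta_eq == pytest.approx(truth["beta_eq"], abs=1e-5)
            assert fit.rate_k == pytest.approx(truth["rate_k"], rel=1e-4)

    def test_fast_kinetics_look_equilibrated(self):
        """A fast-relaxing compound is flat over hourly sampling."""
        cfg = SimulationConfig(seed=9, noise_sigma_points=0.0,
                               rate_range=(50.0, 60.0),
                               sampling_times=tuple(float(t) for t in range(1, 9)))
        series, truth = gen_mutarotation_series(cfg)
        assert is_equilibrated(series, 3.5)
        fit = fit_equilibration(series)
        assert fit.equilibrated_from_start
        assert fit.beta_eq == pytest.approx(truth["beta_eq"], abs=0.2)

    def test_recovery_error_monotone_in_noise(self):
        def rmse(sigma, seed0):
            errs = []
            for i in range(25):
                cfg = SimulationConfig(seed=seed0 + i, noise_sigma_points=sigma,
                                       rate_range=(0.3, 0.7))
                series, truth = gen_mutarotation_series(cfg)
                fit = fit_equilibration(series)
                errs.append((fit.beta_eq - truth["beta_eq"]) ** 2)
            return np.sqrt(np.mean(errs))

        assert rmse(0.5, 100) < rmse(2.0, 100)


class TestNMRGeneration:
    def test_classifier_accuracy_on_draws(self):
        """Configured class separations give >= 99% assignment accuracy."""
        cfg = SimulationConfig(seed=17)
        df = gen_nmr_observables(cfg, n=10_000)
        calls = [classify_anomer(observables_from_row(r)).call
                 for _, r in df.iterrows()]
        acc = np.mean([c == t for c, t in zip(calls, df["true_anomer"])])
        assert acc >= 0.99

    def test_printed_reference_centers_reproduce_calls(self):
        """Centres pinned to the reference compounds give their printed calls."""
        cfg = SimulationConfig(
            seed=1,
            nmr_alpha_params={"j_h1_h2": (3.3, 0.0),
                              "one_bond_j_c1_h1": (165.5, 0.0),
                              "one_bond_j_c1_h1_ac": (177.0, 0.0),
                              "optical_rotation_d": (120.0, 0.0)},
            nmr_beta_params={"j_h1_h2": (8.4, 0.0),
                             "one_bond_j_c1_h1": (153.7, 0.0),
                             "one_bond_j_c1_h1_ac": (166.0, 0.0),
                             "optical_rotation_d": (35.0, 0.0)},
        )
        df = gen_nmr_observables(cfg, n=50, in_pyridine=False)
        for _, row in df.iterrows():
            assert classify_anomer(observables_from_row(row)).call == \
                row["true_anomer"]

    def test_couplings_nonnegative(self):
        df = gen_nmr_observables(SimulationConfig(seed=2), n=500)
        assert (df["j_h1_h2"] >= 0).all()
        assert (df["one_bond_j_c1_h1"] >= 0).all()


class TestTorsionGeneration:
    def test_single_even_term_periodic_with_planted_minima(self):
        cfg = SimulationConfig(torsion_terms=((2.0, 2, 45.0),))
        profile, truth = gen_torsion_profile(cfg)
        assert periodicity_score(profile, 180.0) == pytest.approx(1.0)
        minima = sorted(p.angle for p in scan_extrema(profile)
                        if p.kind == "minimum")
        for found, true in zip(minima, sorted(truth["minima_deg"])):
            assert abs(found - true) < 2.0

    def test_odd_term_breaks_halfturn_periodicity(self):
        cfg = SimulationConfig(torsion_terms=((2.0, 2, 45.0), (1.0, 1, 0.0)))
        profile, _ = gen_torsion_profile(cfg)
        assert periodicity_score(profile, 180.0) < 1.0

    def test_zero_amplitude_is_flat(self):
        cfg = SimulationConfig(torsion_terms=((0.0, 2, 0.0),))
        profile, truth = gen_torsion_profile(cfg)
        assert truth["flat"]
        assert scan_extrema(profile) == []
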