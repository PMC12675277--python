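"""Parameter recovery and diagnostics of the least-squares fitting modes."""

import numpy as np
import pytest

from ckflux import (
    AccumulationAssay,
    AssayDataset,
    KineticParams,
    SimulationDesign,
    UnderdeterminedError,
    fit_dataset_shared,
    fit_single_assay,
    fit_treatment_assay,
    simulate_assay,
    summarize_I,
)
from ckflux.fitting import SolverConfig

F = 0.05


def _make_assay(truth, design, assay_id="a"):
    assay, _ = simulate_assay(truth, design, assay_id=assay_id)
    return assay


class TestSingleAssayFit:
    def test_noiseless_recovery_exact(self, noiseless_design, reference_params):
        assay = _make_assay(reference_params, noiseless_design)
        fit = fit_single_assay(assay, F)
        p = fit.single()
        assert p.I == pytest.approx(reference_params.I, rel=1e-6)
        assert p.E == pytest.approx(reference_params.E, rel=1e-6)
        assert p.K == pytest.approx(reference_params.K, abs=1e-6)
        assert fit.converged

    def test_flat_trace_reports_unidentifiable_efflux(self):
        t = np.linspace(0.0, 900.0, 10)
        assay = AccumulationAssay("flat", t, np.full_like(t, 0.05 * 2.0), c0=2.0, f=F)
        fit = fit_single_assay(assay, F)
        p = fit.single()
        # influx indistinguishable from zero at the data scale
        assert p.I * 900.0 * 2.0 < 2.0 * 1e-1
        assert p.K == pytest.approx(0.05, abs=1e-3)
        assert any("unidentifiable" in n for n in fit.notes)

    def test_doubling_c0_leaves_parameters_unchanged(self, noiseless_design, reference_params):
        a1 = _make_assay(reference_params, noiseless_design)
        from dataclasses import replace

        a2 = _make_assay(reference_params, replace(noiseless_design, c0=4.0))
        p1, p2 = fit_single_assay(a1, F).single(), fit_single_assay(a2, F).single()
        assert p2.I == pytest.approx(p1.I, rel=1e-6)
        assert p2.E == pytest.approx(p1.E, rel=1e-6)

    def test_underdetermined_rejected(self):
        assay = AccumulationAssay("tiny", [0.0, 60.0, 120.0], [0.0, 0.5, 0.9], c0=2.0, f=F)
        with pytest.raises(UnderdeterminedError):
            fit_single_assay(assay, F)

    def test_refit_from_optimum_does_not_increase_objective(self, noiseless_design):
        rng_design = SimulationDesign(
            time_grid=noiseless_design.time_grid, noise_sd=0.04, seed=7
        )
        assay = _make_assay(KineticParams(8e-3, 3e-3, 0.02), rng_design)
        first = fit_single_assay(assay, F)
        p = first.single()
        refit = fit_single_assay(
            assay, F, SolverConfig(guess_I=p.I, guess_E=p.E, guess_K=p.K)
        )
        assert refit.residual_norm <= first.residual_norm * (1 + 1e-9)


class TestSharedFit:
    TRUE_I = [2e-3, 4e-3, 6e-3, 8e-3, 10e-3, 12e-3]
    SHARED_E, SHARED_K = 4e-3, 0.02

    def _dataset(self, design):
        assays = [
            _make_assay(KineticParams(I, self.SHARED_E, self.SHARED_K), design, f"a{i}")
            for i, I in enumerate(self.TRUE_I)
        ]
        return AssayDataset(assays, f=F)

    def test_single_assay_dataset_equals_single_fit(self, noiseless_design, reference_params):
        assay = _make_assay(reference_params, noiseless_design)
        joint = fit_dataset_shared(AssayDataset([assay], f=F))
        single = fit_single_assay(assay, F).single()
        jp = joint.params[assay.assay_id]
        assert jp.I == pytest.approx(single.I, rel=1e-6)
        assert joint.shared_params[0] == pytest.approx(single.E, rel=1e-6)
        assert joint.shared_params[1] == pytest.approx(single.K, abs=1e-6)

    def test_noiseless_exact_recovery_of_all_parameters(self, noiseless_design):
        fit = fit_dataset_shared(self._dataset(noiseless_design))
        E, K = fit.shared_params
        assert E == pytest.approx(self.SHARED_E, rel=1e-6)
        assert K == pytest.approx(self.SHARED_K, rel=1e-6)
        for i, I_true in enumerate(self.TRUE_I):
            assert fit.params[f"a{i}"].I == pytest.approx(I_true, rel=1e-6)

    def test_assay_order_invariance(self, noiseless_design):
        ds = self._dataset(noiseless_design)
        fwd = fit_dataset_shared(ds)
        rev = fit_dataset_shared(AssayDataset(ds.assays[::-1], f=F))
        assert fwd.shared_params[0] == pytest.approx(rev.shared_params[0], abs=1e-8)
        assert fwd.shared_params[1] == pytest.approx(rev.shared_params[1], abs=1e-8)

    def test_identical_assays_match_single_fit(self, noiseless_design, reference_params):
        assays = [
            _make_assay(reference_params, noiseless_design, f"rep{i}") for i in range(3)
        ]
        joint = fit_dataset_shared(AssayDataset(assays, f=F))
        single = fit_single_assay(assays[0], F).single()
        assert joint.shared_params[0] == pytest.approx(single.E, rel=1e-6)
        assert joint.shared_params[1] == pytest.approx(single.K, rel=1e-6)

    def test_noisy_recovery_within_tolerance(self):
        """8 assays, 10 points over 900 s, noise sd 2% of c0: median |dI|/I < 10%, |dE|/E < 15%."""
        rng = np.random.default_rng(11)
        true_I = 17.86e-3 * rng.uniform(0.5, 1.5, 8)
        seeds = np.random.SeedSequence(11).generate_state(8) % (2**31)
        assays = []
        for i in range(8):
            design = SimulationDesign(
                time_grid=tuple(np.linspace(0.0, 900.0, 10)),
                noise_sd=0.04,
                seed=int(seeds[i]),
            )
            assays.append(
                _make_assay(KineticParams(true_I[i], self.SHARED_E, self.SHARED_K), design, f"n{i}")
            )
        fit = fit_dataset_shared(AssayDataset(assays, f=F))
        rel_err_I = [
            abs(fit.params[f"n{i}"].I - true_I[i]) / true_I[i] for i in range(8)
        ]
        assert np.median(rel_err_I) < 0.10
        assert abs(fit.shared_params[0] - self.SHARED_E) / self.SHARED_E < 0.15


class TestTreatmentFit:
    def test_noiseless_recovery(self):
        design = SimulationDesign(
            time_grid=tuple(np.linspace(0.0, 900.0, 16)), noise_sd=0.0, t_prime=420.0
        )
        truth = KineticParams(I=0.02, E=0.004, K=0.02, I_prime=0.002)
        assay = _make_assay(truth, design)
        p = fit_treatment_assay(assay, F).single()
        assert p.I == pytest.approx(truth.I, rel=1e-5)
        assert p.I_prime == pytest.approx(truth.I_prime, rel=1e-5)
        assert p.E == pytest.approx(truth.E, rel=1e-5)
        assert p.K == pytest.approx(truth.K, rel=1e-4)

    def test_unchanged_influx_recovered_as_equal(self):
        design = SimulationDesign(
            time_grid=tuple(np.linspace(0.0, 900.0, 16)), noise_sd=0.0, t_prime=420.0
        )
        truth = KineticParams(I=0.01, E=0.004, K=0.02, I_prime=0.01)
        p = fit_treatment_assay(_make_assay(truth, design), F).single()
        assert p.I_prime == pytest.approx(p.I, rel=1e-3)

    def test_no_post_treatment_points_falls_back_with_warning(self):
        t = np.linspace(0.0, 400.0, 8)
        truth = KineticParams(I=0.01, E=0.004, K=0.0)
        clean = np.asarray(
            [float(v) for v in __import__("ckflux").eval_accumulation(t, truth, 2.0, F)]
        )
        assay = AccumulationAssay("pre", t, clean, c0=2.0, f=F, t_prime=400.0)
        with pytest.warns(UserWarning, match="no points after"):
            fit = fit_treatment_assay(assay, F)
        assert fit.single().I_prime is None


class TestSummarizeI:
    def _fits(self, I_values, group):
        from ckflux.fitting import FitResult

        return [
            FitResult(params={f"{group}{i}": KineticParams(I, 1e-3, 0.0)})
            for i, I in enumerate(I_values)
        ], {f"{group}{i}": group for i in range(len(I_values))}

    def test_odd_count_median(self):
        fits, grouping = self._fits([1e-3, 2e-3, 3e-3], "g")
        table = summarize_I(fits, grouping)
        assert table.loc[0, "median_I"] == pytest.approx(2e-3)

    def test_even_count_midpoint(self):
        fits, grouping = self._fits([1e-3, 2e-3, 3e-3, 4e-3], "g")
        table = summarize_I(fits, grouping)
        assert table.loc[0, "median_I"] == pytest.approx(2.5e-3)

    def test_empty_group_omitted_with_warning(self):
        fits, grouping = self._fits([1e-3, 2e-3, 3e-3], "g")
        grouping["phantom_assay"] = "empty_group"
        with pytest.warns(UserWarning, match="empty_group"):
            table = summarize_I(fits, grouping)
        assert list(table["group"]) == ["g"]

    def test_seeded_noisy_group_median_close_to_truth(self):
        true_I = 17.86e-3
        seeds = np.random.SeedSequence(5).generate_state(10) % (2**31)
        fits = []
        for i in range(10):
            design = SimulationDesign(
                time_grid=tuple(np.linspace(0.0, 900.0, 12)), noise_sd=0.04, seed=int(seeds[i])
            )
            assay = _make_assay(KineticParams(true_I, 4e-3, 0.02), design, f"r{i}")
            fits.append(fit_single_assay(assay, F))
        table = summarize_I(fits, {f"r{i}": "tZ-like" for i in range(10)})
        assert abs(table.loc[0, "median_I"] - true_I) / true_I < 0.10
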