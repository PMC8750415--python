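"""Generator behaviour: design arithmetic, mixing, determinism, artifacts."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from milknir import (BUILTIN_DEVICES, Composition, DeviceProfile,
                     SampleDesign, build_component_library,
                     dose_for_fraud_level, generate_spectra, inject_artifacts,
                     wet_blend_total_solids_pct)
from milknir.synthetic import NITROGEN_MASS_FRACTION, SpectraSet


class TestDesignArithmetic:
    def test_default_design_matches_study(self):
        design = SampleDesign()
        assert design.n_samples_per_mode == 163
        assert design.n_samples == 326
        assert design.n_spectra(n_devices=8) == 26080

    def test_fraud_levels_must_be_positive(self):
        with pytest.raises(ValueError):
            SampleDesign(fraud_levels=(0.0, 5.0))

    def test_wet_blend_recipe_total_solids(self):
        assert wet_blend_total_solids_pct(30.0, 45.0) == pytest.approx(40.0)

    @given(n_cow=st.integers(4, 20), n_buf=st.integers(0, 3),
           n_spiked=st.integers(1, 4), n_rep=st.integers(1, 4),
           n_levels=st.integers(1, 3))
    @settings(max_examples=20, deadline=None)
    def test_row_count_is_samples_times_replicates(self, n_cow, n_buf,
                                                   n_spiked, n_rep, n_levels):
        design = SampleDesign(
            n_cow_smp=n_cow, n_buffalo_mix=n_buf, n_spiked_smps=n_spiked,
            fraud_levels=tuple(2.0 * (i + 1) for i in range(n_levels)),
            blending_modes=("dry",), n_replicates=n_rep, seed=3)
        device = dataclasses.replace(BUILTIN_DEVICES["F"], artifact_rate=0.0)
        spectra = generate_spectra(design, device)
        assert spectra.n_rows == design.n_samples_per_mode * n_rep


class TestComponentLibrary:
    def test_deterministic_for_seed(self):
        grid = np.linspace(900, 1700, 64)
        lib1 = build_component_library(5, grid)
        lib2 = build_component_library(5, grid)
        for name in lib1:
            np.testing.assert_array_equal(lib1[name], lib2[name])

    def test_grid_restriction_is_pointwise(self):
        full = np.linspace(740, 2500, 881)
        sub_mask = (full >= 900) & (full <= 1700)
        lib_full = build_component_library(1, full)
        lib_sub = build_component_library(1, full[sub_mask])
        for name in lib_full:
            np.testing.assert_allclose(lib_sub[name], lib_full[name][sub_mask],
                                       rtol=0, atol=0)

    def test_curves_are_non_negative(self):
        lib = build_component_library(11, np.linspace(740, 2500, 400))
        for name, curve in lib.items():
            assert np.all(curve >= 0), name

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            build_component_library(0, np.array([]))


class TestDosing:
    def test_ammonium_sulfate_nitrogen_mass_fraction(self):
        # 2 x 14.007 / 132.14 from the chemical formula
        assert NITROGEN_MASS_FRACTION["ammonium_sulfate"] == pytest.approx(
            0.2120, abs=2e-4)

    def test_zero_fraud_gives_zero_dose(self):
        for adulterant in ("ammonium_sulfate", "semicarbazide", "cornstarch"):
            assert dose_for_fraud_level(adulterant, 0.0) == 0.0

    def test_nitrogen_basis_dose(self):
        # 5% of total N 5.28 g/100 g at w_N = 0.2120
        dose = dose_for_fraud_level("ammonium_sulfate", 5.0,
                                    Composition(total_nitrogen=5.28))
        assert dose == pytest.approx(0.05 * 5.28 / 0.2120, rel=1e-3)

    def test_cornstarch_lactose_basis(self):
        dose = dose_for_fraud_level("cornstarch", 5.0,
                                    Composition(lactose=52.0))
        assert dose == pytest.approx(0.05 * 52.0 / 0.9)

    def test_unknown_adulterant_and_negative_fraud_rejected(self):
        with pytest.raises(ValueError):
            dose_for_fraud_level("melamine", 5.0)
        with pytest.raises(ValueError):
            dose_for_fraud_level("cornstarch", -1.0)


class TestGeneration:
    def test_deterministic_per_seed(self, small_design, quiet_device_a):
        s1 = generate_spectra(small_design, quiet_device_a)
        s2 = generate_spectra(small_design, quiet_device_a)
        np.testing.assert_array_equal(s1.absorbance, s2.absorbance)
        pd.testing.assert_frame_equal(s1.meta, s2.meta)

    def test_different_seeds_differ(self, small_design, quiet_device_a):
        other = dataclasses.replace(small_design, seed=small_design.seed + 1)
        s1 = generate_spectra(small_design, quiet_device_a)
        s2 = generate_spectra(other, quiet_device_a)
        assert not np.allclose(s1.absorbance, s2.absorbance)

    def test_noise_free_scatter_free_replicates_identical(self, small_design):
        device = dataclasses.replace(BUILTIN_DEVICES["A"], noise_sd=0.0,
                                     artifact_rate=0.0)
        spectra = generate_spectra(small_design, device, scatter=False)
        for _, idx in spectra.meta.groupby(
                ["sample_id", "blending_mode"]).indices.items():
            block = spectra.absorbance[idx]
            assert np.abs(block - block[0]).max() == 0.0

    def test_dose_response_monotone_without_noise(self):
        # every cow SMP is spiked, so the blank centroid coincides with the
        # spiked set's own baseline and the dose term must push the mean
        # squared distance up monotonically
        design = SampleDesign(n_cow_smp=10, n_buffalo_mix=0, n_spiked_smps=10,
                              blending_modes=("dry",), n_replicates=1, seed=2)
        device = dataclasses.replace(BUILTIN_DEVICES["E"], noise_sd=0.0,
                                     artifact_rate=0.0)
        spectra = generate_spectra(design, device, scatter=False)
        meta = spectra.meta
        blank = spectra.absorbance[(meta.role == "cow").to_numpy()]
        centroid = blank.mean(axis=0)
        for adulterant in design.adulterants:
            blank_dist = np.mean(np.sum((blank - centroid) ** 2, axis=1))
            dists = []
            for level in design.fraud_levels:
                rows = spectra.absorbance[
                    ((meta.adulterant == adulterant)
                     & (meta.fraud_level_pct == level)).to_numpy()]
                dists.append(np.mean(np.sum((rows - centroid) ** 2, axis=1)))
            # strictly increasing across fraud levels; the blank comparison
            # uses the top level because the mass-balance dilution at a
            # minute dose can first pull spectra marginally toward the mean
            assert np.all(np.diff(dists) > 0), (adulterant, dists)
            assert dists[-1] > blank_dist

    def test_same_sample_same_composition_across_devices(self, small_design):
        sa = generate_spectra(small_design, BUILTIN_DEVICES["A"])
        sb = generate_spectra(small_design, BUILTIN_DEVICES["B"])
        cols = ["sample_id", "blending_mode", "protein", "lactose",
                "moisture", "fat"]
        pd.testing.assert_frame_equal(
            sa.meta[cols].drop_duplicates().reset_index(drop=True),
            sb.meta[cols].drop_duplicates().reset_index(drop=True))


class TestArtifacts:
    def _flat_set(self, device, n_rows=40):
        grid = device.wavelengths
        absorbance = np.full((n_rows, grid.size), 0.5)
        meta = pd.DataFrame({
            "sample_id": [f"S{i}" for i in range(n_rows)],
            "device_id": device.device_id, "replicate_idx": 1,
            "adulterant": "none", "fraud_level_pct": 0.0,
            "blending_mode": "dry", "dose_g_per_100g": 0.0, "role": "cow",
            "is_outlier_truth": False,
        })
        return SpectraSet(grid, absorbance, meta)

    def test_zero_rate_is_noop(self, small_spectra, quiet_device_a):
        out = inject_artifacts(small_spectra, quiet_device_a, seed=1)
        np.testing.assert_array_equal(out.absorbance, small_spectra.absorbance)
        assert not out.meta.is_outlier_truth.any()

    def test_truth_flags_exactly_the_modified_rows(self):
        device = dataclasses.replace(BUILTIN_DEVICES["G"], artifact_rate=0.4)
        spectra = self._flat_set(device)
        out = inject_artifacts(spectra, device, seed=3)
        changed = np.any(out.absorbance != spectra.absorbance, axis=1)
        np.testing.assert_array_equal(changed,
                                      out.meta.is_outlier_truth.to_numpy())
        assert changed.any()

    def test_fringe_on_flat_spectrum_is_pure_sinusoid(self):
        device = DeviceProfile("X", 900.0, 1700.0, 256,
                               artifact_kinds=frozenset({"fringe"}),
                               artifact_rate=1.0)
        spectra = self._flat_set(device, n_rows=5)
        out = inject_artifacts(spectra, device, seed=9)
        grid = out.wavelengths

        def sinusoid_fit(diff, period):
            design = np.column_stack([np.sin(2 * np.pi * grid / period),
                                      np.cos(2 * np.pi * grid / period)])
            coef, _, _, _ = np.linalg.lstsq(design, diff, rcond=None)
            rss = float(np.sum((diff - design @ coef) ** 2))
            return rss, float(np.hypot(*coef))

        from scipy.optimize import minimize_scalar

        for i in range(out.n_rows):
            diff = out.absorbance[i] - spectra.absorbance[i]
            # coarse grid to localize the period, then refine
            grid_periods = np.linspace(15.0, 70.0, 1200)
            coarse = [sinusoid_fit(diff, p)[0] for p in grid_periods]
            p0 = grid_periods[int(np.argmin(coarse))]
            opt = minimize_scalar(lambda p: sinusoid_fit(diff, p)[0],
                                  bounds=(p0 - 0.1, p0 + 0.1),
                                  method="bounded",
                                  options={"xatol": 1e-12})
            rss, amp = sinusoid_fit(diff, opt.x)
            assert rss < 1e-12 * np.sum(diff ** 2)
            assert 0.02 <= amp <= 0.05

    def test_fixed_steps_share_breakpoints(self):
        device = dataclasses.replace(BUILTIN_DEVICES["F"], artifact_rate=1.0)
        spectra = self._flat_set(device)
        out = inject_artifacts(spectra, device, seed=5)
        k = out.wavelengths.size
        expected = {k // 3, (2 * k) // 3}
        for i in np.flatnonzero(out.meta.is_outlier_truth.to_numpy()):
            diff = np.diff(out.absorbance[i] - spectra.absorbance[i])
            breaks = set(np.flatnonzero(np.abs(diff) > 1e-9) + 1)
            assert breaks == expected
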