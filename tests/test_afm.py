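"""Mechanics: contact point, Hertz fit, hysteresis, adhesion, aggregation."""

import math

import numpy as np
import pandas as pd
import pytest

from ecmmech.afm import (ContactFit, FitOptions, aggregate_hierarchy,
                         analyze_batch, analyze_curve, compute_adhesion,
                         compute_viscosity_index, curve_to_force_indentation,
                         detect_contact_point, fit_hertz_sphere)
from ecmmech.synthetic import CurveGenSpec, generate_curve_batch, generate_force_curve
from ecmmech.types import ForceCurve


def flat_noise_curve(seed=0, n=400):
    rng = np.random.default_rng(seed)
    z = np.linspace(0.0, 3000.0, n)
    d = rng.normal(0.0, 5e-12 / 0.03 * 1e9, n)  # 5 pN of force noise, in nm
    return ForceCurve("flat", z, d, z[::-1], d[::-1], 0.03, 2.5)


class TestContactPoint:
    def test_noiseless_recovery_within_10nm(self, noiseless_curve):
        curve, truth = noiseless_curve
        contact = detect_contact_point(curve)
        assert not contact.flagged
        assert abs(contact.z0 - truth.z0_true) < 10e-9

    def test_all_baseline_curve_is_flagged(self):
        contact = detect_contact_point(flat_noise_curve())
        assert contact.flagged
        assert math.isnan(contact.z0)

    def test_matches_exhaustive_grid_search(self, noiseless_curve):
        """Joint search lands within one sample step of a brute-force scan that
        refits baseline + Hertz slope at every sample position (independent
        numpy implementation)."""
        curve, _ = noiseless_curve
        z = curve.z_app_m()
        F_raw = curve.force_app_N()
        k = curve.k
        best = (np.inf, None)
        for i in range(15, z.size - 20):
            zb, fb = z[: max(0, i - 5)], F_raw[: max(0, i - 5)]
            if zb.size < 10:
                continue
            b, a = np.polyfit(zb, fb, 1)
            F = F_raw - (a + b * z)
            delta = (z - z[i]) - F / k
            m = (z >= z[i]) & (delta > 0)
            if m.sum() < 20:
                continue
            x = delta[m] ** 1.5
            dmax = delta[m].max()
            w = (delta[m] >= 0.1 * dmax) & (delta[m] <= 0.9 * dmax)
            if w.sum() < 20:
                continue
            s = float(x[w] @ F[m][w]) / float(x[w] @ x[w])
            if s <= 0:
                continue
            resid = F.copy()
            resid[m] = F[m] - s * x
            sse = float(resid @ resid)
            if sse < best[0]:
                best = (sse, z[i])
        contact = detect_contact_point(curve, FitOptions(candidate_stride=1))
        step = z[1] - z[0]
        assert abs(contact.z0 - best[1]) <= step


class TestForceIndentation:
    def test_contact_definition_at_z0(self, noiseless_curve):
        curve, truth = noiseless_curve
        contact = ContactFit(z0=truth.z0_true, baseline_offset=0.0, baseline_slope=0.0,
                             sse=0.0)
        delta, F = curve_to_force_indentation(curve, contact)
        i = int(np.argmin(np.abs(curve.z_app_m() - truth.z0_true)))
        step = (curve.z_app_m()[1] - curve.z_app_m()[0])
        # at the sample nearest z0 the indentation is below half a grid step
        # and the force is correspondingly negligible
        assert abs(delta[i]) <= 0.5 * step and abs(F[i]) < 1e-12

    def test_rigid_surface_has_zero_indentation(self):
        z = np.linspace(0, 3000, 200)
        z0 = 1500.0
        defl = np.clip(z - z0, 0, None)  # deflection tracks piezo: infinitely stiff
        curve = ForceCurve("rigid", z, defl, z[::-1], defl[::-1], 0.03, 2.5)
        contact = ContactFit(z0=z0 * 1e-9, baseline_offset=0.0, baseline_slope=0.0,
                             sse=0.0)
        delta, _ = curve_to_force_indentation(curve, contact)
        assert np.abs(delta[z >= z0]).max() < 1e-15

    def test_force_depends_only_on_k_times_deflection(self, noiseless_curve):
        curve, _ = noiseless_curve
        contact = ContactFit(z0=2e-6, baseline_offset=0.0, baseline_slope=0.0, sse=0.0)
        _, F1 = curve_to_force_indentation(curve, contact)
        half = ForceCurve("half-k", curve.z_app_nm, 2 * curve.defl_app_nm,
                          curve.z_ret_nm, 2 * curve.defl_ret_nm,
                          curve.k / 2, curve.R_um)
        _, F2 = curve_to_force_indentation(half, contact)
        np.testing.assert_allclose(F1, F2, rtol=1e-12)


class TestHertzFit:
    def test_noiseless_modulus_within_0p1_percent(self, noiseless_curve):
        curve, truth = noiseless_curve
        row = analyze_curve(curve)
        assert not row["flagged"]
        assert row["E_Pa"] == pytest.approx(470.0, rel=1e-3)

    def test_modulus_linear_in_force_scale(self, noiseless_curve):
        curve, truth = noiseless_curve
        contact = ContactFit(z0=truth.z0_true, baseline_offset=0.0,
                             baseline_slope=0.0, sse=0.0)
        delta, F = curve_to_force_indentation(curve, contact)
        r1 = fit_hertz_sphere(delta, F, curve.R_m, 0.5)
        r2 = fit_hertz_sphere(delta, 2 * F, curve.R_m, 0.5)
        assert r2.E == pytest.approx(2 * r1.E, rel=1e-12)

    def test_matches_grid_search_oracle(self, noiseless_curve):
        """Closed-form slope equals a brute-force 1-D scan over E minimizing
        the window SSE, within one grid step."""
        curve, truth = noiseless_curve
        contact = detect_contact_point(curve)
        delta, F = curve_to_force_indentation(curve, contact)
        fit = fit_hertz_sphere(delta, F, curve.R_m, 0.5, curve_id=curve.curve_id)
        m = delta > 0
        d, f = delta[m], F[m]
        lo, hi = fit.fit_range
        w = (d >= lo) & (d <= hi)
        grid = np.linspace(100.0, 1000.0, 1801)  # 0.5 Pa steps
        pref = (4.0 / 3.0) / (1.0 - 0.25) * math.sqrt(curve.R_m)
        sse = [(np.square(f[w] - pref * E * d[w] ** 1.5)).sum() for E in grid]
        E_grid = grid[int(np.argmin(sse))]
        assert abs(fit.E - E_grid) <= 0.5

    def test_too_few_contact_points_flagged(self):
        fit = fit_hertz_sphere(np.linspace(-1e-6, 1e-8, 30),
                               np.zeros(30), 2.5e-6, 0.5)
        assert fit.flagged


class TestViscosityIndex:
    def test_elastic_curve_has_zero_ratio(self):
        spec = CurveGenSpec(noise_sd=0.0, hysteresis_factor=0.0, adhesion_depth=0.0)
        curve, _ = generate_force_curve(spec)
        row = analyze_curve(curve)
        assert abs(row["hysteresis_ratio"]) < 1e-6

    def test_recovers_generator_hysteresis_factor(self, noiseless_curve):
        curve, truth = noiseless_curve
        row = analyze_curve(curve)
        assert row["hysteresis_ratio"] == pytest.approx(0.3, abs=0.02)

    def test_ratio_invariant_under_common_rescaling(self, noiseless_curve):
        curve, _ = noiseless_curve
        contact = detect_contact_point(curve)
        da, Fa = curve_to_force_indentation(curve, contact, "approach")
        dr, Fr = curve_to_force_indentation(curve, contact, "withdrawal")
        r1 = compute_viscosity_index(da, Fa, dr, Fr).hysteresis_ratio
        r2 = compute_viscosity_index(da, 7.0 * Fa, dr, 7.0 * Fr).hysteresis_ratio
        assert r2 == pytest.approx(r1, rel=1e-12)

    def test_zero_approach_area_flagged(self):
        d = np.linspace(0, 1e-6, 50)
        out = compute_viscosity_index(d, np.zeros(50), d, np.zeros(50))
        assert out.flagged


class TestAdhesion:
    def test_injected_well_depth_recovered_exactly(self):
        spec = CurveGenSpec(adhesion_depth=1.02e-9, noise_sd=0.0)
        curve, _ = generate_force_curve(spec)
        contact = detect_contact_point(curve)
        adh = compute_adhesion(curve, contact)
        assert adh.F_adh_nN == pytest.approx(1.02, rel=1e-3)

    def test_purely_repulsive_withdrawal_gives_zero(self):
        spec = CurveGenSpec(adhesion_depth=0.0, noise_sd=0.0)
        curve, _ = generate_force_curve(spec)
        contact = ContactFit(z0=2e-6, baseline_offset=0.0, baseline_slope=0.0, sse=0.0)
        assert compute_adhesion(curve, contact).F_adh_nN == 0.0

    def test_invariant_under_constant_offset_before_baseline_correction(self):
        spec = CurveGenSpec(adhesion_depth=1.5e-9, noise_sd=0.0)
        curve, _ = generate_force_curve(spec)
        shifted = ForceCurve("shift", curve.z_app_nm,
                             curve.defl_app_nm + 0.5e-9 / curve.k * 1e9,
                             curve.z_ret_nm,
                             curve.defl_ret_nm + 0.5e-9 / curve.k * 1e9,
                             curve.k, curve.R_um)
        a1 = analyze_curve(curve)["F_adh_nN"]
        a2 = analyze_curve(shifted)["F_adh_nN"]
        assert a2 == pytest.approx(a1, abs=1e-3)


class TestAggregation:
    @staticmethod
    def _df(values, **labels):
        rows = []
        for i, v in enumerate(values):
            rows.append({"sample": labels.get("sample", "s0"), "region": 0,
                         "point": 0, "replicate": i, "E_Pa": v,
                         "hysteresis_ratio": 0.1, "F_adh_nN": 1.0,
                         "flagged": False, "flag_reason": "",
                         "age": "young", "volume": "RV"})
        return pd.DataFrame(rows)

    def test_replicates_average_to_point_mean(self):
        agg = aggregate_hierarchy(self._df([1000, 2000, 3000, 4000, 5000]))
        assert agg["point"].E_Pa.iloc[0] == 3000

    def test_group_mean_and_se_match_hand_computation(self):
        # samples 0.40/0.44/0.48/0.56 kPa -> mean 0.47, SE = SD/sqrt(4) = 0.0342
        rows = []
        for s, v in enumerate([400.0, 440.0, 480.0, 560.0]):
            df = self._df([v])
            df["sample"] = f"s{s}"
            rows.append(df)
        agg = aggregate_hierarchy(pd.concat(rows, ignore_index=True))
        grp = agg["group"].iloc[0]
        assert grp["E_Pa_mean"] == pytest.approx(470.0)
        assert grp["E_Pa_se"] == pytest.approx(34.157, abs=0.01)

    def test_single_sample_group_has_missing_se(self):
        agg = aggregate_hierarchy(self._df([1.0, 2.0]))
        assert math.isnan(agg["group"].iloc[0]["E_Pa_se"])

    def test_permutation_invariance_within_levels(self, rng):
        base = pd.concat([self._df(rng.normal(500, 50, 4)) for _ in range(3)],
                         ignore_index=True)
        base["region"] = np.repeat([0, 1, 2], 4)
        shuffled = base.sample(frac=1.0, random_state=1).reset_index(drop=True)
        a = aggregate_hierarchy(base)
        b = aggregate_hierarchy(shuffled)
        pd.testing.assert_frame_equal(
            a["sample"].reset_index(drop=True), b["sample"].reset_index(drop=True))

    def test_flagged_curves_excluded_and_counted(self):
        df = self._df([1000.0, 2000.0, np.nan])
        df.loc[2, "flagged"] = True
        df.loc[2, "flag_reason"] = "negative Hertz slope"
        agg = aggregate_hierarchy(df)
        assert agg["qc"]["n_flagged"] == 1
        assert agg["point"].E_Pa.iloc[0] == 1500.0


class TestRecoveryProperties:
    def test_modulus_monotone_in_ground_truth(self):
        """Median recovered modulus strictly increases with the generative one
        across matched noise seeds (small batches)."""
        medians = []
        for E in (260.0, 360.0, 470.0, 540.0):
            spec = CurveGenSpec(E_true=E, noise_sd=5e-12, seed=77)
            batch = generate_curve_batch(spec, 1, 2, 4)
            df = analyze_batch(batch)
            medians.append(df.E_Pa.median())
        assert all(a < b for a, b in zip(medians, medians[1:]))
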