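"""Generators: determinism, ground-truth self-consistency, spec validation."""

import numpy as np
import pytest

from pvrassays.imaging import local_entropy
from pvrassays.molecular import ddct_fold_change
from pvrassays.synthetic import (
    CtTableSpec,
    FluorFieldSpec,
    PackingError,
    PhaseFieldSpec,
    SolubilisationSpec,
    SpecError,
    WoundSeriesSpec,
    generate_ct_table,
    generate_fluor_field,
    generate_phase_field,
    generate_solubilisation,
    generate_wound_series,
)


class TestDeterminism:
    def test_phase_field_bit_identical(self):
        a, ta = generate_phase_field(PhaseFieldSpec(height=96, width=96, confluence_target=40, seed=5))
        b, tb = generate_phase_field(PhaseFieldSpec(height=96, width=96, confluence_target=40, seed=5))
        np.testing.assert_array_equal(a.pixels, b.pixels)
        np.testing.assert_array_equal(ta.data["mask"], tb.data["mask"])

    def test_fluor_field_bit_identical(self):
        spec = FluorFieldSpec(height=256, width=256, n_nuclei=20, positive_fraction=0.5, seed=2)
        a405, a488, ta = generate_fluor_field(spec)
        b405, b488, tb = generate_fluor_field(spec)
        np.testing.assert_array_equal(a405.pixels, b405.pixels)
        np.testing.assert_array_equal(a488.pixels, b488.pixels)
        np.testing.assert_array_equal(ta.data["positive"], tb.data["positive"])

    def test_wound_solubilisation_ct_bit_identical(self):
        w1, _ = generate_wound_series(WoundSeriesSpec(height=96, width=96, seed=3))
        w2, _ = generate_wound_series(WoundSeriesSpec(height=96, width=96, seed=3))
        for f1, f2 in zip(w1, w2):
            np.testing.assert_array_equal(f1.pixels, f2.pixels)
        c1 = generate_solubilisation(SolubilisationSpec(noise_sd=0.1, seed=9))
        c2 = generate_solubilisation(SolubilisationSpec(noise_sd=0.1, seed=9))
        np.testing.assert_array_equal(c1.delta_absorbance, c2.delta_absorbance)
        t1 = generate_ct_table(CtTableSpec(ct_noise_sd=0.3, seed=4))
        t2 = generate_ct_table(CtTableSpec(ct_noise_sd=0.3, seed=4))
        assert t1.equals(t2)

    def test_seed_changes_pixels(self):
        a, _ = generate_phase_field(PhaseFieldSpec(height=96, width=96, confluence_target=40, seed=0))
        b, _ = generate_phase_field(PhaseFieldSpec(height=96, width=96, confluence_target=40, seed=1))
        assert not np.array_equal(a.pixels, b.pixels)


class TestPhaseField:
    def test_zero_confluence_is_empty(self):
        frame, truth = generate_phase_field(PhaseFieldSpec(confluence_target=0, seed=0))
        assert truth.data["area_fraction_pct"] == 0.0
        assert truth.data["mask"].sum() == 0

    def test_full_confluence_is_full(self):
        _, truth = generate_phase_field(PhaseFieldSpec(confluence_target=100, seed=0))
        assert truth.data["area_fraction_pct"] == 100.0

    def test_target_25_within_one_point_by_recount(self):
        frame, truth = generate_phase_field(PhaseFieldSpec(confluence_target=25, seed=1))
        recount = 100.0 * truth.data["mask"].mean()
        assert recount == pytest.approx(truth.data["area_fraction_pct"])
        assert 24.0 <= recount <= 26.0

    def test_entropy_contrast_inside_vs_outside(self):
        frame, truth = generate_phase_field(PhaseFieldSpec(confluence_target=40, seed=2))
        ent = local_entropy(frame, 9)
        mask = truth.data["mask"]
        assert ent[mask].mean() - ent[~mask].mean() >= 1.0

    def test_impossible_radius_raises_packing_error(self):
        with pytest.raises(PackingError):
            generate_phase_field(
                PhaseFieldSpec(height=64, width=64, confluence_target=50,
                               cell_radius_range=(30, 60), seed=0)
            )

    def test_spec_validation(self):
        with pytest.raises(SpecError):
            PhaseFieldSpec(confluence_target=101)
        with pytest.raises(SpecError):
            PhaseFieldSpec(height=32)
        with pytest.raises(SpecError):
            PhaseFieldSpec(noise_sd=-1)


class TestFluorField:
    def test_positive_fraction_zero_and_one(self):
        spec0 = FluorFieldSpec(height=256, width=256, n_nuclei=15, positive_fraction=0.0, seed=1)
        _, _, t0 = generate_fluor_field(spec0)
        assert t0.data["n_positive"] == 0 and not t0.data["positive"].any()
        spec1 = FluorFieldSpec(height=256, width=256, n_nuclei=15, positive_fraction=1.0, seed=1)
        _, _, t1 = generate_fluor_field(spec1)
        assert t1.data["n_positive"] == 15 and t1.data["positive"].all()

    def test_positive_count_rounds_half_away_from_zero(self):
        spec = FluorFieldSpec(n_nuclei=200, positive_fraction=0.3578, seed=7)
        _, _, truth = generate_fluor_field(spec)
        assert truth.data["n_positive"] == 72  # round(71.56)
        assert int(truth.data["positive"].sum()) == 72

    def test_ground_truth_consistent_with_emitted_channels(self):
        f405, f488, truth = generate_fluor_field(
            FluorFieldSpec(height=256, width=256, n_nuclei=12, positive_fraction=0.5,
                           noise_sd=0.0, seed=3)
        )
        mask = truth.data["nuclei_mask"]
        # emitted 405 intensity is confined to the ground-truth nuclei mask
        assert f405.pixels[~mask].max() == 0.0
        assert f405.pixels[mask].mean() > 10
        # per-nucleus 488 levels match the assigned means
        for (cy, cx), r, assigned in zip(
            truth.data["centres"], truth.data["radii"], truth.data["mean_488_assigned"]
        ):
            val = f488.pixels[int(round(cy)), int(round(cx))]
            assert val == pytest.approx(assigned, abs=1e-9)

    def test_min_separation_respected(self):
        spec = FluorFieldSpec(height=320, width=320, n_nuclei=30, positive_fraction=0.5, seed=5)
        _, _, truth = generate_fluor_field(spec)
        c = truth.data["centres"]
        d = np.sqrt(((c[:, None, :] - c[None, :, :]) ** 2).sum(-1))
        np.fill_diagonal(d, np.inf)
        assert d.min() >= spec.min_separation

    def test_impossible_packing_raises(self):
        with pytest.raises(PackingError):
            generate_fluor_field(
                FluorFieldSpec(height=128, width=128, n_nuclei=200, min_separation=50, seed=0)
            )

    def test_threshold_straddling_specs_rejected(self):
        with pytest.raises(SpecError):
            FluorFieldSpec(positive_488_mean=9.0)
        with pytest.raises(SpecError):
            FluorFieldSpec(negative_488_mean=11.0)


class TestWoundSeries:
    def test_constant_targets_give_constant_area(self):
        frames, truth = generate_wound_series(
            WoundSeriesSpec(height=96, width=96, timepoints=(0, 12, 24),
                            recovery_targets=(0, 0, 0), seed=1)
        )
        assert len(set(truth.data["wound_areas_px"])) == 1

    def test_full_recovery_gives_fully_textured_frame(self):
        frames, truth = generate_wound_series(
            WoundSeriesSpec(height=96, width=96, timepoints=(0, 36),
                            recovery_targets=(0, 100), seed=1)
        )
        assert truth.data["wound_areas_px"][-1] == 0

    def test_half_recovery_halves_area_within_one_percent(self):
        frames, truth = generate_wound_series(
            WoundSeriesSpec(height=200, width=200, timepoints=(0, 12),
                            recovery_targets=(0, 50), initial_wound_fraction=0.25, seed=2)
        )
        a0, a1 = truth.data["wound_areas_px"]
        assert a1 == pytest.approx(a0 / 2, rel=0.01)

    def test_horizontal_orientation(self):
        frames, truth = generate_wound_series(
            WoundSeriesSpec(height=96, width=96, wound_orientation="horizontal", seed=0)
        )
        assert truth.data["baseline_area_px"] > 0

    def test_spec_validation(self):
        with pytest.raises(SpecError):
            WoundSeriesSpec(recovery_targets=(0, 60, 50, 70))  # not nondecreasing
        with pytest.raises(SpecError):
            WoundSeriesSpec(timepoints=(0, 12, 12, 36))
        with pytest.raises(SpecError):
            WoundSeriesSpec(recovery_targets=(5, 25, 50, 75))  # nonzero at t=0


class TestSolubilisation:
    def test_noiseless_segments_exactly_collinear(self):
        spec = SolubilisationSpec(
            concentrations=(0.005, 0.01, 0.02, 0.05, 0.1, 0.2),
            breakpoint=0.03, noise_sd=0.0,
        )
        curve = generate_solubilisation(spec)
        c, y = curve.concentration, curve.delta_absorbance
        left = c <= spec.breakpoint
        for seg in (left, ~left):
            slopes = np.diff(y[seg]) / np.diff(c[seg])
            np.testing.assert_allclose(slopes, slopes[0], rtol=1e-12)

    def test_breakpoint_outside_range_rejected(self):
        with pytest.raises(SpecError):
            SolubilisationSpec(breakpoint=5.0)

    def test_slope_ordering_enforced(self):
        with pytest.raises(SpecError):
            SolubilisationSpec(unimeric_slope=30.0, micellar_slope=20.0)


class TestCtTable:
    def test_zero_fold_changes_give_flat_ddct(self):
        table = generate_ct_table(CtTableSpec(ct_noise_sd=0.0, seed=0))
        fc = ddct_fold_change(table)
        np.testing.assert_allclose(fc["delta_delta_ct"], 0.0, atol=1e-12)

    def test_one_doubling_lowers_target_ct_by_one_cycle(self):
        spec = CtTableSpec(
            genes=("Snai1",),
            true_log2_fold_changes={("Snai1", "treated"): 1.0},
            ct_noise_sd=0.0, seed=0,
        )
        table = generate_ct_table(spec)
        mean_ct = table.groupby(["gene", "condition"])["ct"].mean()
        assert mean_ct[("Snai1", "control")] - mean_ct[("Snai1", "treated")] == pytest.approx(1.0)
        assert mean_ct[("Gapdh", "control")] == mean_ct[("Gapdh", "treated")]

    def test_noiseless_recovery_to_machine_precision(self, rng):
        genes = ("A", "B", "C", "D")
        conditions = ("control", "low", "high")
        lfc = {
            (g, cond): (0.0 if cond == "control" else float(rng.normal(0, 2)))
            for g in genes
            for cond in conditions
        }
        table = generate_ct_table(CtTableSpec(
            genes=genes, conditions=conditions, true_log2_fold_changes=lfc,
            ct_noise_sd=0.0, seed=1,
        ))
        fc = ddct_fold_change(table)
        for row in fc.itertuples():
            assert row.log2_fold_change == pytest.approx(lfc[(row.gene, row.condition)], abs=1e-9)

    def test_control_must_have_zero_fold_change(self):
        with pytest.raises(SpecError):
            CtTableSpec(true_log2_fold_changes={("Snai1", "control"): 1.0})
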