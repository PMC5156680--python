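"""Chemical-shift chi-square, NOE averaging, restraint categories, RMSIP, tautomer rule."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from scanpsn import synthetic as syn
from scanpsn.ensemble import ConformationalEnsemble, ResidueId
from scanpsn.nmr import (NoeRestraint, PredictedShiftSeries, ShiftRecord, categorize_restraint, chi2_shifts,
                         his_tautomer, noe_differences, read_noe_table,
                         rmsip, running_chi2, write_noe_table)

from conftest import build_ensemble, point_residue


def shift_pair(resnum, exp_value, predicted_values, atom="CA", chain="A"):
    rid = ResidueId(chain, resnum, "ALA")
    return (PredictedShiftSeries(rid, atom, np.asarray(predicted_values, float)),
            ShiftRecord(rid, atom, exp_value))


class TestChi2:
    def test_exact_agreement_is_zero(self):
        truth = pd.DataFrame({"chain": "A", "resnum": range(1, 6), "resname": "ALA",
                              "atom": "CA", "shift": [50.0, 51, 52, 53, 54]})
        experimental, predicted = syn.make_shift_data(truth, n_frames=10, noise_sd=0.0)
        report = chi2_shifts(predicted, experimental)
        assert report.overall == 0.0
        assert report.per_group["CA"] == 0.0

    def test_hand_computed_example(self):
        """s=2, experiment {4,4}, frame means {5,3} -> chi2 = 1/4 + 1/4 = 0.5."""
        p1, e1 = shift_pair(1, 4.0, [5.0, 5.0])
        p2, e2 = shift_pair(2, 4.0, [3.0, 3.0])
        report = chi2_shifts([p1, p2], [e1, e2])
        assert report.overall == pytest.approx(0.5)
        assert report.s_total == 2

    def test_constant_offset_closed_form(self):
        """Predictions = experiment + c give chi2 = (s/(s-1)) * mean(c^2/d_exp)."""
        c = 0.8
        exps = [4.0, 5.0, 8.0, 10.0, 2.5]
        pairs = [shift_pair(i + 1, d, [d + c] * 3) for i, d in enumerate(exps)]
        report = chi2_shifts([p for p, _ in pairs], [e for _, e in pairs])
        s = len(exps)
        expected = (s / (s - 1)) * np.mean([c ** 2 / d for d in exps])
        assert report.overall == pytest.approx(expected)

    def test_invariant_to_frame_and_record_order(self):
        rng = np.random.default_rng(0)
        pairs = [shift_pair(i + 1, 5.0 + i, rng.normal(5.0 + i, 0.5, 20))
                 for i in range(6)]
        predicted = [p for p, _ in pairs]
        experimental = [e for _, e in pairs]
        base = chi2_shifts(predicted, experimental).overall
        shuffled_frames = [PredictedShiftSeries(p.residue, p.atom, p.values[::-1])
                           for p in predicted]
        assert chi2_shifts(shuffled_frames, experimental).overall == pytest.approx(base)
        assert chi2_shifts(predicted[::-1], experimental[::-1]).overall == pytest.approx(base)

    def test_noise_increases_expected_chi2(self):
        """Mean chi2 over replicates grows monotonically with frame-noise variance."""
        truth = pd.DataFrame({"chain": "A", "resnum": range(1, 9), "resname": "ALA",
                              "atom": "CA", "shift": np.linspace(4, 12, 8)})
        means = []
        for i, sd in enumerate([0.1, 0.4, 1.0]):
            reps = []
            for rep in range(200):
                exp, pred = syn.make_shift_data(truth, n_frames=5, noise_sd=sd,
                                                seed=1000 * i + rep)
                reps.append(chi2_shifts(pred, exp).overall)
            means.append(np.mean(reps))
        assert means[0] < means[1] < means[2]

    def test_unmatched_series_rejected(self):
        p, e = shift_pair(1, 4.0, [4.0])
        orphan, _ = shift_pair(99, 4.0, [4.0])
        with pytest.raises(ValueError, match="99"):
            chi2_shifts([p, orphan], [e])

    def test_zero_experimental_shift_rejected(self):
        rid = ResidueId("A", 1, "ALA")
        with pytest.raises(ValueError):
            ShiftRecord(rid, "CA", 0.0)

    def test_single_shift_group_rejected(self):
        p, e = shift_pair(1, 4.0, [4.0])
        with pytest.raises(ValueError):
            chi2_shifts([p], [e])


class TestRunningChi2:
    def test_full_window_matches_direct_statistic(self):
        rng = np.random.default_rng(2)
        pairs = [shift_pair(i + 1, 5.0, rng.normal(5, 0.3, 12)) for i in range(4)]
        predicted = [p for p, _ in pairs]
        experimental = [e for _, e in pairs]
        curve = running_chi2(predicted, experimental, [3, 6, 12])
        assert curve["chi2"].iloc[-1] == pytest.approx(
            chi2_shifts(predicted, experimental).overall)

    def test_single_frame_window_uses_that_frame(self):
        p1, e1 = shift_pair(1, 4.0, [5.0, 4.0])
        p2, e2 = shift_pair(2, 4.0, [3.0, 4.0])
        curve = running_chi2([p1, p2], [e1, e2], [1])
        assert curve["chi2"].iloc[0] == pytest.approx(0.5)

    def test_stationary_curve_flattens(self):
        """With a stationary systematic offset the curve converges to its bias term."""
        rng = np.random.default_rng(8)
        exps = np.linspace(4, 12, 10)
        predicted, experimental = [], []
        for i, d in enumerate(exps):
            p, e = shift_pair(i + 1, d, d + 0.5 + rng.normal(0, 0.5, 400))
            predicted.append(p)
            experimental.append(e)
        curve = running_chi2(predicted, experimental, [200, 400])
        half, last = curve["chi2"]
        assert abs(last - half) < 0.10 * last

    def test_window_beyond_frames_rejected(self):
        p, e = shift_pair(1, 4.0, [4.0, 4.0])
        p2, e2 = shift_pair(2, 5.0, [5.0, 5.0])
        with pytest.raises(ValueError):
            running_chi2([p, p2], [e, e2], [3])


class TestNoe:
    def _static_pair_ensemble(self, distances):
        """One frame per distance; the two CB atoms sit that far apart in x."""
        frames = []
        for d in distances:
            frames.append([point_residue("A", 1, (0.0, 0.0, 0.0)),
                           point_residue("A", 10, (d, 0.0, 0.0))])
        base = build_ensemble(frames[0], n_frames=len(distances))
        coords = base.coords.copy()
        for f, frame in enumerate(frames):
            ens_f = build_ensemble(frame)
            coords[f] = ens_f.coords[0]
        return ConformationalEnsemble(
            coords=coords, residues=base.residues, atom_names=base.atom_names,
            atom_elements=base.atom_elements,
            atom_residue_index=base.atom_residue_index, masses=base.masses)

    def test_exact_distance_gives_zero_difference(self):
        ens = self._static_pair_ensemble([0.4, 0.4])
        r = NoeRestraint(ens.residues[0], "CB", ens.residues[1], "CB", 0.4)
        table = noe_differences(ens, [r])
        assert table["difference"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_linear_average_is_arithmetic_mean(self):
        ens = self._static_pair_ensemble([0.3, 0.5])
        r = NoeRestraint(ens.residues[0], "CB", ens.residues[1], "CB", 0.35)
        table = noe_differences(ens, [r], averaging="linear")
        assert table["distance_avg"].iloc[0] == pytest.approx(0.4)

    def test_r6_average_below_linear(self):
        ens = self._static_pair_ensemble([0.3, 0.5])
        r = NoeRestraint(ens.residues[0], "CB", ens.residues[1], "CB", 0.35)
        linear = noe_differences(ens, [r], averaging="linear")["distance_avg"].iloc[0]
        r6 = noe_differences(ens, [r], averaging="r6")["distance_avg"].iloc[0]
        assert r6 < linear

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(min_value=0.1, max_value=1.0), min_size=2, max_size=12))
    def test_r6_never_exceeds_linear(self, distances):
        """Power-mean inequality: (mean d^-6)^(-1/6) <= mean d for any series."""
        ens = self._static_pair_ensemble(distances)
        r = NoeRestraint(ens.residues[0], "CB", ens.residues[1], "CB", 0.35)
        linear = noe_differences(ens, [r], averaging="linear")["distance_avg"].iloc[0]
        r6 = noe_differences(ens, [r], averaging="r6")["distance_avg"].iloc[0]
        assert r6 <= linear + 1e-12

    def test_missing_atom_names_restraint(self):
        ens = self._static_pair_ensemble([0.4])
        r = NoeRestraint(ens.residues[0], "SG", ens.residues[1], "CB", 0.4)
        with pytest.raises(KeyError, match="SG"):
            noe_differences(ens, [r])

    @pytest.mark.parametrize("res_a,res_b,chain_b,expected", [
        (10, 15, "A", "long"),           # separation 5 > 4
        (10, 14, "A", "short"),          # separation exactly 4
        (10, 12, "A", "short"),
        (10, 15, "B", "intermolecular"),
    ])
    def test_categorization_rule(self, res_a, res_b, chain_b, expected):
        r = NoeRestraint(ResidueId("A", res_a, "ALA"), "CB",
                         ResidueId(chain_b, res_b, "ALA"), "CB", 0.5)
        assert categorize_restraint(r) == expected

    def test_categories_partition_total(self):
        ens = syn.make_dimer_ensemble(5, 12, seed=0)
        restraints = syn.make_noe_set(ens, (10, 20, 5), seed=1)
        counts = pd.Series([categorize_restraint(r) for r in restraints]).value_counts()
        assert counts.sum() == len(restraints) == 35

    def test_table_round_trip(self, tmp_path):
        ens = syn.make_dimer_ensemble(3, 8, seed=2)
        restraints = syn.make_noe_set(ens, (3, 5, 2), jitter=0.02, seed=3)
        path = tmp_path / "noe.tsv"
        write_noe_table(restraints, path)
        back = read_noe_table(path)
        assert len(back) == len(restraints)
        assert [r.category for r in back] == [r.category for r in restraints]


def wobble_ensemble(mode, n_frames=30, amp=0.02, seed=0):
    """CA-only chain oscillating along one displacement mode (+ small noise).

    The base geometry is deliberately non-collinear so the rigid-body fit is
    well conditioned.
    """
    base = np.array([[0.0, 0.00, 0.00], [0.4, 0.10, 0.00], [0.8, 0.00, 0.15],
                     [1.2, 0.20, 0.05], [1.6, 0.05, 0.20], [2.0, 0.15, 0.10]])
    rng = np.random.default_rng(seed)
    frames = []
    for f in range(n_frames):
        t = np.sin(2 * np.pi * f / n_frames + rng.normal(0, 0.1))
        frames.append(base + amp * t * mode + rng.normal(0, amp * 0.02, base.shape))
    residues = [ResidueId("A", i + 1, "ALA") for i in range(6)]
    return ConformationalEnsemble(
        coords=np.stack(frames), residues=residues,
        atom_names=["CA"] * 6, atom_elements=["C"] * 6,
        atom_residue_index=np.arange(6))


class TestRmsip:
    # torque- and translation-free orthogonal displacement patterns
    MODE_Y = np.column_stack([np.zeros(6), [1, -1, -1, 1, 0, 0], np.zeros(6)])
    MODE_Z = np.column_stack([np.zeros(6), np.zeros(6), [1, -1, -1, 1, 0, 0]])

    def test_self_overlap_is_one(self):
        ens = wobble_ensemble(self.MODE_Y, seed=1)
        assert rmsip(ens, ens, n_modes=3) == pytest.approx(1.0, abs=1e-10)

    def test_symmetry(self):
        a = wobble_ensemble(self.MODE_Y, seed=1)
        b = wobble_ensemble(self.MODE_Z, seed=2)
        assert rmsip(a, b, n_modes=3) == pytest.approx(rmsip(b, a, n_modes=3), abs=1e-10)

    def test_orthogonal_dominant_modes_near_zero(self):
        a = wobble_ensemble(self.MODE_Y, seed=1)
        b = wobble_ensemble(self.MODE_Z, seed=2)
        assert rmsip(a, b, n_modes=1) < 0.2

    def test_matches_independent_svd_oracle(self):
        """RMSIP equals a from-scratch SVD/rotation-library computation to 1e-8."""
        rng = np.random.default_rng(7)
        mode = rng.normal(size=(6, 3))
        a = wobble_ensemble(self.MODE_Y + 0.3 * mode, seed=3)
        b = wobble_ensemble(self.MODE_Z + 0.1 * mode, seed=4)
        n_modes = 4

        def oracle_modes(ens):
            X = ens.coords.copy()
            X -= X.mean(axis=1, keepdims=True)
            ref = X[0]
            for _ in range(2):
                aligned = []
                for frame in X:
                    rot, _ = Rotation.align_vectors(ref, frame)
                    aligned.append(rot.apply(frame))
                aligned = np.stack(aligned)
                ref = aligned.mean(axis=0)
                ref -= ref.mean(axis=0)
            flat = aligned.reshape(len(aligned), -1)
            flat = flat - flat.mean(axis=0)
            _, _, vt = np.linalg.svd(flat, full_matrices=False)
            return vt[:n_modes].T

        V, W = oracle_modes(a), oracle_modes(b)
        expected = float(np.sqrt(np.sum((V.T @ W) ** 2) / n_modes))
        assert rmsip(a, b, n_modes=n_modes) == pytest.approx(expected, abs=1e-8)

    def test_bounded_in_unit_interval(self):
        rng = np.random.default_rng(11)
        for seed in range(3):
            a = wobble_ensemble(rng.normal(size=(6, 3)), seed=seed)
            b = wobble_ensemble(rng.normal(size=(6, 3)), seed=seed + 10)
            value = rmsip(a, b, n_modes=5)
            assert 0.0 <= value <= 1.0 + 1e-12

    def test_mismatched_atom_sets_rejected(self):
        a = wobble_ensemble(self.MODE_Y)
        b_res = [ResidueId("B", i + 1, "ALA") for i in range(6)]
        b = ConformationalEnsemble(coords=a.coords.copy(), residues=b_res,
                                   atom_names=["CA"] * 6, atom_elements=["C"] * 6,
                                   atom_residue_index=np.arange(6))
        with pytest.raises(ValueError, match="mismatched"):
            rmsip(a, b, n_modes=2)

    def test_too_few_frames_rejected(self):
        ens = wobble_ensemble(self.MODE_Y, n_frames=5)
        with pytest.raises(ValueError, match="n_modes"):
            rmsip(ens, ens, n_modes=20)


class TestHisTautomer:
    @pytest.mark.parametrize("shift,expected", [
        (120.0, "NE2-H"),
        (125.0, "ND1-H"),
        (122.0, "ND1-H"),  # strict boundary
    ])
    def test_cd2_shift_rule(self, shift, expected):
        assert his_tautomer(shift) == expected

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            his_tautomer(float("nan"))
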