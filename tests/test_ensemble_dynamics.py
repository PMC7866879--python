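import numpy as np
import pytest

from conftest import random_rotation
from varimpact.ensemble_dynamics import (
    Ensemble,
    ReplicateSet,
    bfactor_agreement,
    classify_mobility,
    ensemble_from_structures,
    exclude_outlier_replicates,
    median_rmsd,
    rmsd_score,
    rmsd_series,
    rmsf,
    rmsf_compare,
    BOLTZMANN_B_FACTOR,
)
from varimpact.structure_io import Selection
from varimpact.synthetic_data import EnsembleSpec, make_ensemble, make_structure


def constant_ensemble(structure, n_frames=5, label="wild_type", rep="rep1"):
    frames = np.repeat(structure.coords[None], n_frames, axis=0)
    return Ensemble(frames, structure, replicate_id=rep, label=label)


class TestRmsdSeries:
    def test_identical_frames_all_zero(self, helix):
        series = rmsd_series(constant_ensemble(helix))
        np.testing.assert_allclose(series, 0.0, atol=1e-10)

    def test_rigid_motion_removed(self, helix):
        rng = np.random.default_rng(0)
        frames = []
        for _ in range(4):
            rot = random_rotation(rng)
            frames.append(helix.coords @ rot.T + rng.standard_normal(3))
        ens = Ensemble(np.array(frames), helix)
        np.testing.assert_allclose(rmsd_series(ens), 0.0, atol=1e-8)

    def test_direct_formula_oracle(self, helix):
        """Two atoms pushed apart along their axis in frame 2 only: the
        displacement has no rigid component, so RMSD = d·sqrt(2/n)."""
        coords = helix.coords
        frames = np.repeat(coords[None], 3, axis=0)
        sel = Selection.calpha()
        idx = sel.indices(helix)
        n = len(idx)
        d = 0.1
        i, j = idx[0], idx[-1]
        u = coords[j] - coords[i]
        u /= np.linalg.norm(u)
        frames[1, i] -= d * u
        frames[1, j] += d * u
        ens = Ensemble(frames, helix)
        series = rmsd_series(ens, selection=sel)
        assert series[0] == pytest.approx(0.0, abs=1e-9)
        assert series[2] == pytest.approx(0.0, abs=1e-9)
        assert series[1] == pytest.approx(d * np.sqrt(2.0 / n), rel=1e-3)


class TestMedianRmsd:
    @pytest.mark.parametrize(
        "series,window,expect",
        [
            (np.full(10, 2.5), None, 2.5),
            (np.array([1.0, 2, 3, 4, 5]), None, 3.0),
        ],
    )
    def test_simple_medians(self, series, window, expect):
        assert median_rmsd(series, window) == expect

    def test_last_window_matches_sort_oracle(self):
        rng = np.random.default_rng(1)
        series = rng.gamma(2.0, 1.0, size=1000)
        window = slice(500, 1000)
        expect = np.sort(series[500:])[249:251].mean()
        assert median_rmsd(series, window) == pytest.approx(expect)


def _replicate_set(structure, medians, n_frames=20):
    """Replicates whose production-window RMSD medians are forced exactly.

    Frames expand radially about the centroid; a radial expansion has no
    rigid-motion component, so the Kabsch fit leaves it intact and the RMSD
    from frame 0 is beta * radius of gyration, solved for the wanted value.
    """
    coords = structure.coords
    centroid = coords.mean(axis=0)
    rg = np.sqrt(np.mean(np.sum((coords - centroid) ** 2, axis=1)))
    ensembles = []
    for i, m in enumerate(medians):
        frames = np.repeat(coords[None], n_frames, axis=0)
        beta = m / rg
        for f in range(1, n_frames):
            frames[f] = coords + beta * (coords - centroid)
        ensembles.append(
            Ensemble(frames, structure, replicate_id=f"rep{i + 1}", label="x")
        )
    return ReplicateSet(ensembles, production_window=slice(n_frames // 2, n_frames))


class TestOutlierExclusion:
    def test_identical_replicates_none_excluded(self, helix):
        rset = _replicate_set(helix, [1.5] * 10)
        out = exclude_outlier_replicates(rset)
        assert out.excluded == {}

    def test_single_deviant_excluded(self, helix):
        """MAD of {1.5 x9, 4.0} is 0, so the 4.0 replicate deviates."""
        rset = _replicate_set(helix, [1.5] * 9 + [4.0])
        out = exclude_outlier_replicates(rset)
        assert list(out.excluded) == ["rep10"]
        assert "4.000" in out.excluded["rep10"]

    def test_cap_keeps_worst_two(self, helix):
        rset = _replicate_set(helix, [1.5] * 7 + [3.0, 4.0, 5.0])
        out = exclude_outlier_replicates(rset, max_excluded=2)
        assert set(out.excluded) == {"rep10", "rep9"}

    def test_all_flagged_refuses(self, helix):
        rset = _replicate_set(helix, [1.0, 2.0, 8.0, 9.0])
        out = exclude_outlier_replicates(rset, k=0.0)
        assert "__warning__" in out.excluded
        assert len(out.retained) == 4

    def test_planted_outlier_recovered(self, helix):
        spec = EnsembleSpec(
            n_residues=12, sigma=0.2, n_frames=60, n_replicates=6,
            n_outliers=1, outlier_inflation=2.5, seed=7,
        )
        rset = make_ensemble(helix, spec)
        out = exclude_outlier_replicates(rset)
        assert list(out.excluded) == rset.truth["outlier_replicates"] == ["rep6"]


class TestRmsdScore:
    def test_same_data_zero_diff(self, helix):
        rset = _replicate_set(helix, [1.5] * 4)
        score = rmsd_score(rset, [rset])
        assert score["median_diff"] == pytest.approx(0.0, abs=1e-12)

    def test_constructed_difference(self, helix):
        variant = _replicate_set(helix, [1.66] * 4)
        baseline = _replicate_set(helix, [1.50] * 4)
        score = rmsd_score(variant, [baseline])
        assert score["median_diff"] == pytest.approx(0.16, abs=1e-9)
        assert score["percent_change"] == pytest.approx(100 * 0.16 / 1.5, abs=1e-6)

    def test_baseline_is_mean_of_sets(self, helix):
        variant = _replicate_set(helix, [1.5] * 4)
        b1 = _replicate_set(helix, [1.4] * 4)
        b2 = _replicate_set(helix, [1.6] * 4)
        assert rmsd_score(variant, [b1, b2])["baseline_median"] == pytest.approx(1.5)

    def test_empty_baseline_raises(self, helix):
        with pytest.raises(ValueError, match="baseline"):
            rmsd_score(_replicate_set(helix, [1.0] * 3), [])


class TestRmsf:
    def test_identical_frames_zero(self, helix):
        prof = rmsf(constant_ensemble(helix, 6))
        assert all(v == pytest.approx(0.0, abs=1e-10) for v in prof.values.values())

    def test_two_point_alternation(self, helix):
        """One atom alternating ±d along x has RMSF exactly d (no refit)."""
        d = 0.4
        coords = helix.coords
        frames = np.repeat(coords[None], 6, axis=0)
        idx = Selection.calpha().indices(helix)[5]
        frames[::2, idx, 0] += d
        frames[1::2, idx, 0] -= d
        ens = Ensemble(frames, helix)
        # fit on the untouched atoms so superposition is the identity
        fit = Selection(residue_ranges=((1, 4),), atom_names="backbone")
        prof = rmsf(ens, fit_selection=fit)
        moved_key = helix.residue_keys[idx]
        assert prof.values[moved_key] == pytest.approx(d, abs=1e-9)

    def test_gaussian_sigma_recovery(self):
        """Per-coordinate sigma=0.3 gives per-residue RMSF ≈ 0.3·sqrt(3)."""
        st = make_structure(20, "helix")
        spec = EnsembleSpec(n_residues=20, sigma=0.3, n_frames=500,
                            n_replicates=1, seed=11)
        rset = make_ensemble(st, spec)
        prof = rmsf(rset.ensembles[0], production_window=slice(0, 500))
        mean_rmsf = prof.as_array().mean()
        assert mean_rmsf == pytest.approx(0.3 * np.sqrt(3), rel=0.05)

    def test_rigid_motion_invariance(self, helix):
        rng = np.random.default_rng(3)
        spec = EnsembleSpec(n_residues=12, sigma=0.2, n_frames=40,
                            n_replicates=1, seed=5)
        rset = make_ensemble(helix, spec)
        ens = rset.ensembles[0]
        rot = random_rotation(rng)
        moved = Ensemble(ens.frames @ rot.T + np.array([1.0, 2, 3]), helix)
        a = rmsf(ens, production_window=slice(0, 40)).as_array()
        b = rmsf(moved, production_window=slice(0, 40)).as_array()
        np.testing.assert_allclose(a, b, atol=1e-8)

    def test_planted_window_effect_detected(self):
        """sigma x1.5 in a 20-residue window separates variant from a second
        wild-type realisation by at least 2x in avg_abs_diff."""
        from varimpact.synthetic_data import VariantEffectSpec

        st = make_structure(50, "helix")
        spec = lambda seed: EnsembleSpec(n_residues=50, sigma=0.3, n_frames=200,
                                         n_replicates=1, seed=seed)
        wt1 = rmsf(make_ensemble(st, spec(1)).ensembles[0],
                   production_window=slice(0, 200))
        wt2 = rmsf(make_ensemble(st, spec(2)).ensembles[0],
                   production_window=slice(0, 200))
        effect = VariantEffectSpec(label="v", rmsf_multiplier=1.5,
                                   rmsf_window=(20, 39))
        var = rmsf(make_ensemble(st, spec(3), effect).ensembles[0],
                   production_window=slice(0, 200))
        null = rmsf_compare(wt1, wt2)["avg_abs_diff"]
        planted = rmsf_compare(wt1, var)["avg_abs_diff"]
        assert planted >= 2 * null


class TestRmsfCompare:
    def make_profile(self, values, label=""):
        from varimpact.ensemble_dynamics import RmsfProfile
        from varimpact.structure_io import ResidueKey

        return RmsfProfile(
            {ResidueKey("A", i + 1, "", "ALA"): v for i, v in enumerate(values)},
            label=label,
        )

    def test_identical_profiles(self):
        p = self.make_profile([0.5, 0.7, 0.9, 1.1])
        out = rmsf_compare(p, p)
        assert out["avg_abs_diff"] == 0.0
        assert out["abs_residual_sum"] == 0.0
        assert out["pearson"] == pytest.approx(1.0)
        assert out["spearman"] == pytest.approx(1.0)

    def test_uniform_shift(self):
        wt = self.make_profile([0.5, 0.7, 0.9, 1.1])
        var = self.make_profile([0.6, 0.8, 1.0, 1.2])
        out = rmsf_compare(wt, var)
        assert out["avg_abs_diff"] == pytest.approx(0.1)
        assert out["avg_diff"] == pytest.approx(-0.1)  # wt − variant
        assert out["spearman"] == pytest.approx(1.0)

    def test_brute_force_formulas(self):
        rng = np.random.default_rng(4)
        a = rng.uniform(0.2, 1.5, 50)
        b = rng.uniform(0.2, 1.5, 50)
        out = rmsf_compare(self.make_profile(a), self.make_profile(b))
        from scipy.stats import pearsonr, spearmanr

        assert out["avg_abs_diff"] == pytest.approx(np.abs(a - b).mean())
        assert out["avg_diff"] == pytest.approx((a - b).mean())
        assert out["abs_residual_sum"] == pytest.approx(np.abs(a - b).sum())
        assert out["pearson"] == pytest.approx(pearsonr(a, b).statistic)
        assert out["spearman"] == pytest.approx(spearmanr(a, b).statistic)

    def test_too_few_shared_residues(self):
        with pytest.raises(ValueError, match="3 shared"):
            rmsf_compare(self.make_profile([1.0, 2.0]), self.make_profile([1.0, 2.0]))


class TestBfactorAgreement:
    def test_closed_form_prediction(self, helix):
        from varimpact.ensemble_dynamics import RmsfProfile

        prof = RmsfProfile(
            {k: 1.0 + 0.01 * i for i, k in enumerate(helix.residues())}
        )
        out = bfactor_agreement(prof, helix)
        predicted = list(out["predicted_b"].values())
        assert predicted[0] == pytest.approx(8 * np.pi**2 / 3, abs=1e-9)
        assert BOLTZMANN_B_FACTOR == pytest.approx(26.3189, abs=1e-3)

    def test_affine_pattern_gives_perfect_pearson(self, helix):
        from varimpact.ensemble_dynamics import RmsfProfile

        rng = np.random.default_rng(5)
        for key, atom in helix:
            atom.b_factor = 10.0 + 5.0 * key.resseq
        # choose RMSF so predicted B is affine in crystal B
        prof = RmsfProfile(
            {k: float(np.sqrt((3.0 + 2.0 * (10.0 + 5.0 * k.resseq)) / BOLTZMANN_B_FACTOR))
             for k in helix.residues()}
        )
        out = bfactor_agreement(prof, helix)
        assert out["pearson"] == pytest.approx(1.0, abs=1e-12)

    def test_zero_profile_rejected(self, helix):
        from varimpact.ensemble_dynamics import RmsfProfile

        prof = RmsfProfile({k: 0.0 for k in helix.residues()})
        with pytest.raises(ValueError, match="correlation undefined"):
            bfactor_agreement(prof, helix)


class TestMobility:
    @pytest.mark.parametrize(
        "value,expect",
        [(0.5, "still"), (1.21, "mobile"), (0.7, "intermediate"),
         (1.0, "intermediate"), (0.85, "intermediate")],
    )
    def test_thresholds(self, value, expect):
        from varimpact.ensemble_dynamics import RmsfProfile
        from varimpact.structure_io import ResidueKey

        prof = RmsfProfile({ResidueKey("A", 1, "", "ALA"): value})
        assert classify_mobility(prof)[ResidueKey("A", 1, "", "ALA")] == expect
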