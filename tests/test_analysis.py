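import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from conftest import make_bead_chain, random_rotation
from ubisax.analysis import (PowerLawFit, WeightedEnsemble, average_structure,
                             bound_like_probability, classify_open,
                             compact_fraction, contact_map, end_to_end, fes2d,
                             fit_power_law, kabsch_transform,
                             min_chain_length_for_two_dimers,
                             min_core_distance, predict_linkage_scaling,
                             rmsd_to_reference)
from ubisax.chain import build_topology
from ubisax.synthetic import (GeneratorConfig, surrogate_topology,
                              synth_chain_ensemble, synth_reference_bound_pair)

KT = 2.494


def pair_chain(p0, p1):
    """Two single-bead, single-residue domains at given positions."""
    top = build_topology(2, residues_per_domain=1, core_span=1)
    return make_bead_chain([p0, p1], residues=[1, 2], domains=[0, 1]), top


class TestFes2d:
    def test_uniform_samples_flat(self, rng):
        n = 20000
        frames = [None] * n  # CVs passed as arrays; frames unused
        ens = WeightedEnsemble(frames, np.ones(n), build_topology(1))
        a = rng.uniform(0, 1, n)
        b = rng.uniform(0, 1, n)
        surf = fes2d(ens, a, b, bins=4, kT=1.0)
        spread = np.nanmax(surf.free_energy) - np.nanmin(surf.free_energy)
        assert spread < 0.15  # sampling noise only

    def test_gaussian_curvature(self, rng):
        n = 200000
        sig_a, sig_b = 0.7, 1.3
        a = rng.normal(scale=sig_a, size=n)
        b = rng.normal(scale=sig_b, size=n)
        ens = WeightedEnsemble([None] * n, np.ones(n), build_topology(1))
        surf = fes2d(ens, a, b, bins=41, kT=1.0,
                     ranges=[[-2 * sig_a, 2 * sig_a], [-2 * sig_b, 2 * sig_b]])
        ca = 0.5 * (surf.edges_a[:-1] + surf.edges_a[1:])
        cb = 0.5 * (surf.edges_b[:-1] + surf.edges_b[1:])
        mid_b = len(cb) // 2
        prof_a = surf.free_energy[:, mid_b]
        coef = np.polyfit(ca, prof_a, 2)
        assert coef[0] == pytest.approx(1.0 / (2 * sig_a ** 2), rel=0.1)

    def test_weight_scaling_invariance(self, rng):
        n = 500
        a, b = rng.normal(size=(2, n))
        w = rng.random(n)
        e1 = WeightedEnsemble([None] * n, w, build_topology(1))
        e2 = WeightedEnsemble([None] * n, 2 * w, build_topology(1))
        s1 = fes2d(e1, a, b, bins=5)
        s2 = fes2d(e2, a, b, bins=5)
        assert np.allclose(s1.free_energy, s2.free_energy, equal_nan=True)

    def test_min_is_zero_and_empty_bins_nan(self, rng):
        a = np.concatenate([np.zeros(50), np.ones(50) * 10])
        ens = WeightedEnsemble([None] * 100, np.ones(100), build_topology(1))
        surf = fes2d(ens, a, a, bins=5)
        assert np.nanmin(surf.free_energy) == 0.0
        assert np.isnan(surf.free_energy).any()


class TestMinCoreDistance:
    def test_overlapping_cores(self):
        chain, top = pair_chain([0, 0, 0], [0, 0, 0])
        assert min_core_distance(chain, top, 0, 1) == 0.0

    def test_two_single_beads(self):
        chain, top = pair_chain([0, 0, 0], [0, 0, 2])
        assert min_core_distance(chain, top, 0, 1) == pytest.approx(2.0)

    def test_brute_force(self, rng):
        ens = synth_chain_ensemble(GeneratorConfig(n_domains=2, frames=1,
                                                   mode="two_state", seed=51))
        f = ens.frames[0]
        top = ens.topology
        lo0, hi0 = top.core_ranges[0]
        lo1, hi1 = top.core_ranges[1]
        p0 = f.positions[(f.residue_index >= lo0) & (f.residue_index <= hi0)]
        p1 = f.positions[(f.residue_index >= lo1) & (f.residue_index <= hi1)]
        expected = min(np.linalg.norm(a - b) for a in p0 for b in p1)
        assert min_core_distance(f, top, 0, 1) == pytest.approx(expected)


class TestClassifyOpen:
    @pytest.mark.parametrize("d,label", [(0.61, "open"), (0.60, "compact"),
                                         (0.0, "compact"), (5.0, "open")])
    def test_threshold(self, d, label):
        assert classify_open(d) == label

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            classify_open(-0.1)

    def test_fractions_sum_to_one(self):
        ens = synth_chain_ensemble(GeneratorConfig(n_domains=3, frames=60,
                                                   mode="two_state", seed=52))
        for k in range(2):
            fc = compact_fraction(ens, k, k + 1)
            fo = sum(w for f, w in zip(ens.frames, ens.weights)
                     if classify_open(min_core_distance(f, ens.topology,
                                                        k, k + 1)) == "open")
            assert fc + fo == pytest.approx(1.0)


class TestContactMap:
    def test_no_contacts_all_zero(self):
        ens = synth_chain_ensemble(GeneratorConfig(n_domains=2, frames=10,
                                                   mode="two_state",
                                                   p_compact=0.0, seed=53))
        cm = contact_map(ens, 0, 1, contact_cutoff=0.3)
        assert cm.shape == (12, 12)
        assert np.all(cm == 0)

    def test_single_pair_contact(self):
        top = build_topology(2, residues_per_domain=2, core_span=1)
        chain = make_bead_chain([[0, 0, 0], [5, 0, 0], [0, 0.4, 0]],
                                residues=[1, 2, 3], domains=[0, 0, 1])
        ens = WeightedEnsemble([chain], np.ones(1), top)
        cm = contact_map(ens, 0, 1, contact_cutoff=0.5)
        assert cm.shape == (1, 1)
        assert cm[0, 0] == 1.0

    def test_values_are_probabilities(self):
        ens = synth_chain_ensemble(GeneratorConfig(n_domains=2, frames=40,
                                                   mode="two_state",
                                                   p_compact=0.8, seed=54))
        cm = contact_map(ens, 0, 1)
        assert np.all((cm >= 0) & (cm <= 1))
        assert cm.max() > 0


class TestEndToEnd:
    def test_straight_chain(self):
        top = build_topology(1, residues_per_domain=5, core_span=5)
        pos = np.column_stack([np.linspace(0, 2, 5), np.zeros(5), np.zeros(5)])
        chain = make_bead_chain(pos)
        assert end_to_end(chain, top) == pytest.approx(2.0)

    def test_single_domain_surrogate(self):
        ens = synth_chain_ensemble(GeneratorConfig(n_domains=1, frames=3,
                                                   mode="saw", seed=55))
        vals = [end_to_end(f, ens.topology) for f in ens.frames]
        assert np.allclose(vals, vals[0])  # rigid body: constant e2e
        assert vals[0] > 2.0

    def test_coordinate_oracle(self, rng):
        ens = synth_chain_ensemble(GeneratorConfig(n_domains=3, frames=1,
                                                   mode="two_state", seed=56))
        f = ens.frames[0]
        expected = np.linalg.norm(f.positions[-1] - f.positions[0])
        # first bead is residue 1, last bead is the final residue
        assert end_to_end(f, ens.topology) == pytest.approx(expected)


class TestPowerLaw:
    def test_exact_recovery_of_printed_fit(self):
        n = np.arange(1, 5)
        y = 3.81 * n ** 0.62
        fit = fit_power_law(n, y)
        assert fit.prefactor == pytest.approx(3.81, abs=1e-6)
        assert fit.exponent == pytest.approx(0.62, abs=1e-6)

    def test_constant_data_zero_exponent(self):
        fit = fit_power_law([1, 2, 3, 4], [2.5] * 4)
        assert fit.exponent == pytest.approx(0.0, abs=1e-8)

    def test_scale_equivariance(self, rng):
        n = np.arange(1, 7)
        y = 2.0 * n ** 0.55 * np.exp(rng.normal(scale=0.01, size=6))
        f1 = fit_power_law(n, y)
        f2 = fit_power_law(n, 3.0 * y)
        assert f2.prefactor == pytest.approx(3.0 * f1.prefactor, rel=1e-8)
        assert f2.exponent == pytest.approx(f1.exponent, abs=1e-8)

    def test_noisy_recovery_within_ci(self, rng):
        from scipy.stats import t as t_dist
        crit = t_dist.ppf(0.975, df=4)  # 6 points, 2 parameters
        hits = 0
        for _ in range(100):
            n = np.arange(1, 7)
            y = 3.0 * n ** 0.6 * (1 + rng.normal(scale=0.03, size=6))
            fit = fit_power_law(n, y)
            if abs(fit.exponent - 0.6) <= crit * fit.exponent_stderr:
                hits += 1
        assert hits >= 90

    def test_fixed_exponent_mode(self):
        n = np.arange(1, 5)
        y = 2.2 * n ** 0.6
        fit = fit_power_law(n, y, mode="fixed-exponent")
        assert fit.exponent == 0.6
        assert fit.prefactor == pytest.approx(2.2, rel=1e-10)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            fit_power_law([1, 2], [1.0, -1.0])


class TestLinkagePrediction:
    def test_unit_prefactor(self):
        assert predict_linkage_scaling(1.0, 1) == pytest.approx(1.0)

    def test_printed_prefactor_at_n1(self):
        assert predict_linkage_scaling(3.81, 1, exponent=0.62) == pytest.approx(3.81)

    def test_formula_oracle(self, rng):
        a, nu = rng.uniform(0.5, 5), rng.uniform(0.3, 0.9)
        n = int(rng.integers(1, 10))
        assert predict_linkage_scaling(a, n, nu) == pytest.approx(a * n ** nu)

    def test_invalid_n(self):
        with pytest.raises(ValueError):
            predict_linkage_scaling(1.0, 0)


class TestMinChainLength:
    def test_printed_estimate(self):
        fit = PowerLawFit(3.81, 0.62)
        assert min_chain_length_for_two_dimers(fit, 11.4) == 8

    def test_zero_span(self):
        assert min_chain_length_for_two_dimers(PowerLawFit(1.0, 0.6), 0.0) == 3

    def test_brute_force_scan(self, rng):
        for _ in range(20):
            a = rng.uniform(0.5, 5)
            nu = rng.uniform(0.3, 0.9)
            span = rng.uniform(0, 30)
            fit = PowerLawFit(a, nu)
            got = min_chain_length_for_two_dimers(fit, span)
            brute = next(n for n in range(3, 100000)
                         if a * (n - 2) ** nu >= span)
            assert got == brute


class TestRmsd:
    def test_rigid_copy_zero(self, rng):
        pos = rng.normal(size=(20, 3))
        rot = random_rotation(rng)
        moved = pos @ rot.T + rng.normal(size=3)
        assert rmsd_to_reference(moved, pos) == pytest.approx(0.0, abs=1e-9)

    def test_uniform_displacement_removed_by_superposition(self, rng):
        pos = rng.normal(size=(15, 3))
        shifted = pos + np.array([0.7, 0, 0])
        # a pure translation is removed, RMSD 0
        assert rmsd_to_reference(shifted, pos) == pytest.approx(0.0, abs=1e-9)

    def test_matches_scipy_align_vectors(self, rng):
        a = rng.normal(size=(30, 3))
        b = rng.normal(size=(30, 3))
        got = rmsd_to_reference(a, b)
        rot, rssd = Rotation.align_vectors(b - b.mean(0), a - a.mean(0))
        assert got == pytest.approx(rssd / np.sqrt(30), rel=1e-6)

    def test_count_mismatch(self):
        with pytest.raises(ValueError):
            rmsd_to_reference(np.zeros((3, 3)), np.zeros((4, 3)))

    def test_average_structure_of_rigid_copies(self, rng):
        pos = rng.normal(size=(12, 3))
        copies = [pos @ random_rotation(rng).T + rng.normal(size=3)
                  for _ in range(5)]
        mean = average_structure(copies)
        assert rmsd_to_reference(mean, pos) == pytest.approx(0.0, abs=1e-6)


class TestBoundLike:
    def test_reference_copies_probability_one(self):
        ref, _ = synth_reference_bound_pair()
        top = surrogate_topology(2)
        ens = WeightedEnsemble([ref] * 5, np.ones(5), top)
        res = bound_like_probability(ens, ref)
        assert res.aggregate == pytest.approx(1.0)
        assert res.per_pair[0] == pytest.approx(1.0)

    def test_clash_excluded_needs_surrogate(self):
        ref, _ = synth_reference_bound_pair()
        ens = WeightedEnsemble([ref], np.ones(1), surrogate_topology(2))
        with pytest.raises(ValueError):
            bound_like_probability(ens, ref, mode="clash-excluded")

    def test_clash_excluded_never_exceeds_any_pair(self):
        cfg = GeneratorConfig(n_domains=4, frames=150, mode="bound_like",
                              p_bound=0.3, seed=57)
        ens = synth_chain_ensemble(cfg)
        ref, nemo = synth_reference_bound_pair(cfg)
        any_pair = bound_like_probability(ens, ref)
        excl = bound_like_probability(ens, ref, mode="clash-excluded",
                                      nemo_surrogate=nemo)
        assert excl.aggregate <= any_pair.aggregate + 1e-12
        assert np.all(excl.per_pair <= any_pair.per_pair + 1e-12)
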