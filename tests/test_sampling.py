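import numpy as np
import pytest
from scipy.integrate import quad
from scipy.special import logsumexp

from ubisax.chain import build_elastic_network
from ubisax.cvs import enumerate_cv_set
from ubisax.sampling import (BiasState, HillRecord, ToyPotentialParams,
                             pbmetad_bias, reweight_final_bias, run_metad_1d,
                             run_sampler, toy_energy, wt_hill_height)
from ubisax.synthetic import GeneratorConfig, synth_chain_ensemble

KT = 2.494


def make_bias(n_cvs=1, edges=(-3.0, 3.0), width=0.15, **kw):
    return BiasState(cv_labels=[f"cv{k}" for k in range(n_cvs)],
                     grid_edges=[edges] * n_cvs,
                     widths=np.full(n_cvs, width), kT=KT, **kw)


def chain_bias(cv_set, n_domains):
    edges, widths = [], []
    for d in cv_set:
        if d.kind == "core_distance":
            edges.append((0.0, 6.0 * n_domains)); widths.append(0.25)
        elif d.kind == "interdomain_torsion":
            edges.append((-np.pi, np.pi)); widths.append(0.25)
        elif d.kind == "backbone_rg":
            edges.append((0.0, 4.0 * n_domains)); widths.append(0.15)
        else:
            edges.append((0.0, 4.0)); widths.append(0.2)
    return BiasState(cv_labels=[d.label for d in cv_set], grid_edges=edges,
                     widths=np.array(widths), kT=KT)


class TestToyEnergy:
    def test_reference_geometry_zero(self):
        ens = synth_chain_ensemble(GeneratorConfig(n_domains=2, frames=1,
                                                   mode="two_state", seed=41))
        chain = ens.frames[0]
        en = build_elastic_network(chain, ens.topology, cutoff=1.5)
        params = ToyPotentialParams(bond_k=0.0)
        e = toy_energy(chain, params, ens.topology, en)
        assert e == pytest.approx(0.0, abs=1e-9)

    def test_hardcore_overlap_is_infinite(self):
        from conftest import make_bead_chain
        chain = make_bead_chain([[0, 0, 0], [0.1, 0, 0]], residues=[1, 2],
                                domains=[0, 1])
        from ubisax.chain import build_topology
        top = build_topology(2, residues_per_domain=1, core_span=1)
        assert toy_energy(chain, ToyPotentialParams(), top) == np.inf

    def test_matches_term_oracle(self, rng):
        ens = synth_chain_ensemble(GeneratorConfig(n_domains=2, frames=1,
                                                   mode="two_state", seed=42))
        chain = ens.frames[0]
        top = ens.topology
        en = build_elastic_network(chain, top, cutoff=1.5)
        moved = chain.transformed(translation=np.zeros(3))
        moved.positions = moved.positions + rng.normal(scale=0.01,
                                                       size=moved.positions.shape)
        params = ToyPotentialParams()
        # brute-force elastic + bond terms
        e_en = sum(0.5 * en.force_constant
                   * (np.linalg.norm(moved.positions[a] - moved.positions[b]) - r0) ** 2
                   for (a, b), r0 in zip(en.member_pairs, en.reference_distances))
        linkers = set()
        for lo, hi in top.linker_ranges:
            linkers.update(range(lo, hi + 1))
        bb = np.where(moved.backbone)[0]
        e_bond = 0.0
        for a, b in zip(bb[:-1], bb[1:]):
            if (moved.residue_index[a] in linkers
                    or moved.residue_index[b] in linkers):
                r = np.linalg.norm(moved.positions[a] - moved.positions[b])
                e_bond += 0.5 * params.bond_k * (r - params.bond_length) ** 2
        e = toy_energy(moved, params, top, en)
        assert e == pytest.approx(e_en + e_bond, rel=1e-9)


class TestHillHeight:
    def test_zero_bias_gives_base(self):
        assert wt_hill_height(0.0, 0.1, 10.0, KT) == pytest.approx(0.1)

    def test_one_e_fold(self):
        v = KT * 9.0
        assert wt_hill_height(v, 0.1, 10.0, KT) == pytest.approx(0.1 / np.e)

    def test_formula_oracle(self, rng):
        v = rng.uniform(0, 20)
        expected = 0.075 * np.exp(-v / (KT * 9.0))
        assert wt_hill_height(v, 0.075, 10.0, KT) == pytest.approx(expected)

    def test_gamma_must_exceed_one(self):
        with pytest.raises(ValueError):
            wt_hill_height(1.0, 0.1, 1.0, KT)


class TestPbMetadBias:
    def test_all_zero_biases(self):
        bias = make_bias(n_cvs=4)
        v = pbmetad_bias(np.zeros(4), bias)
        assert v == pytest.approx(-KT * np.log(4))

    def test_single_cv_reduces_to_its_bias(self):
        bias = make_bias(n_cvs=1)
        bias.deposit(np.array([0.5]))
        x = 0.4
        assert pbmetad_bias(np.array([x]), bias) == pytest.approx(
            bias.bias_values([x])[0])

    def test_logsumexp_oracle(self, rng):
        bias = make_bias(n_cvs=3)
        for _ in range(5):
            bias.deposit(rng.uniform(-2, 2, size=3))
        s = rng.uniform(-2, 2, size=3)
        v = bias.bias_values(s)
        expected = -KT * logsumexp(-v / KT)
        assert pbmetad_bias(s, bias) == pytest.approx(expected)

    def test_hill_record_validation(self):
        with pytest.raises(ValueError):
            HillRecord(0, 0.0, -0.1, 0.1, 0, 0)
        with pytest.raises(ValueError):
            HillRecord(0, 0.0, 0.1, -0.1, 0, 0)

    def test_well_tempered_heights_decay_at_revisited_center(self):
        bias = make_bias(n_cvs=1)
        for _ in range(30):
            bias.deposit(np.array([0.0]))
        heights = [h.height for h in bias.hills]
        assert all(b <= a + 1e-12 for a, b in zip(heights, heights[1:]))
        assert heights[-1] < heights[0]


class TestReweightFinalBias:
    def test_zero_bias_uniform(self):
        bias = make_bias(n_cvs=1)
        w = reweight_final_bias(np.linspace(-1, 1, 20)[:, None], bias)
        assert np.allclose(w, 1 / 20)

    def test_weights_normalized(self, rng):
        bias = make_bias(n_cvs=1)
        for _ in range(10):
            bias.deposit(rng.uniform(-2, 2, size=1))
        w = reweight_final_bias(rng.uniform(-2, 2, size=(50, 1)), bias)
        assert w.sum() == pytest.approx(1.0)
        assert np.all(w >= 0)


class TestDoubleWell:
    @staticmethod
    def potential(x):
        # ~15 kT barrier: unreachable for plain MC at this budget
        return 35.0 * (x * x - 1.0) ** 2 + 2.0 * x

    def test_metadynamics_crosses_barrier_unbiased_does_not(self):
        bias = make_bias(base_height=0.5, hill_stride=100)
        xs, _ = run_metad_1d(self.potential, -1.0, 30000, bias, seed=9,
                             step_size=0.25)
        # unbiased MC from the same start: zero-height hills
        flat = make_bias(base_height=0.0, hill_stride=100)
        xs0, _ = run_metad_1d(self.potential, -1.0, 30000, flat, seed=9,
                              step_size=0.25)
        assert (xs > 0.5).sum() > 100
        assert (xs0 > 0.5).sum() == 0

    def test_free_energy_difference_recovered(self):
        za = quad(lambda x: np.exp(-self.potential(x) / KT), -3, 0)[0]
        zb = quad(lambda x: np.exp(-self.potential(x) / KT), 0, 3)[0]
        df_exact = -KT * np.log(zb / za)
        bias = make_bias(base_height=0.5, hill_stride=100)
        xs, bias = run_metad_1d(self.potential, -1.0, 150000, bias, seed=3,
                                step_size=0.25)
        x = xs[40000:]
        w = reweight_final_bias(x[:, None], bias)
        df_est = -KT * np.log(w[x >= 0].sum() / w[x < 0].sum())
        assert abs(df_est - df_exact) < 0.5 * KT


@pytest.fixture(scope="module")
def system():
    ens = synth_chain_ensemble(GeneratorConfig(n_domains=2, frames=2,
                                               mode="two_state", seed=21))
    return ens, enumerate_cv_set(ens.topology)


class TestRunSampler:
    def test_acceptance_in_open_interval(self, system):
        ens, cv_set = system
        res = run_sampler(ens.frames, ens.topology, 300, ToyPotentialParams(),
                          cv_set, seed=7)
        assert 0.0 < res.acceptance_rate < 1.0
        assert np.all(np.isfinite(res.energies))

    def test_identical_seeds_identical_logs(self, system):
        ens, cv_set = system
        kwargs = dict(n_steps=250, potential=ToyPotentialParams(), seed=11)
        r1 = run_sampler(ens.frames, ens.topology, cv_set=cv_set,
                         bias=chain_bias(cv_set, 2), **kwargs)
        r2 = run_sampler(ens.frames, ens.topology, cv_set=cv_set,
                         bias=chain_bias(cv_set, 2), **kwargs)
        assert np.array_equal(r1.cv_log, r2.cv_log, equal_nan=True)

    def test_restrained_run_logs_scaling_offset(self, system):
        from ubisax.metainference import MetainferenceParams, RestraintSet
        from ubisax.saxs import FormFactorTable, restraint_grid
        ens, cv_set = system
        grid = restraint_grid(0.05, 2.0, 11)
        from ubisax.saxs import ensemble_average_intensity
        table = FormFactorTable.uniform()
        data = ensemble_average_intensity(ens.frames, ens.weights, grid, table)
        restraints = RestraintSet(grid, data.intensity,
                                  0.02 * np.abs(data.intensity))
        res = run_sampler(ens.frames, ens.topology, 60, ToyPotentialParams(),
                          cv_set, seed=13, restraints=restraints, table=table,
                          mi_params=MetainferenceParams())
        assert len(res.params_log) == 12
        for _, s, o in res.params_log:
            assert 0.9 <= s <= 1.1 and -1 <= o <= 1
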