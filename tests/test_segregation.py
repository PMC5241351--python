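import numpy as np
import pytest

from mesomix import (ClusterSpec, MixtureSpec, MolecularConfiguration,
                     OccupancyDistribution, PartitionSpec, SimulationBox,
                     build_distribution, count_occupancy, gen_mixture_trajectory,
                     gen_random_mixture, non_ideality, sample_null_ensemble,
                     trajectory_non_ideality)


def _dist(fractions, species="alcohol"):
    return OccupancyDistribution(np.asarray(fractions, dtype=float),
                                 n_boxes_total=1000, species=species)


class TestCountOccupancy:
    def test_single_water_in_first_cell(self):
        box = SimulationBox((10.0, 10.0, 10.0))
        cfg = MolecularConfiguration(species=np.array(["water"], dtype=object), box=box,
                                     elements=np.array(["O", "H", "H"], dtype=object),
                                     coords=[[0.1, 0.1, 0.1], [1.0, 0.1, 0.1], [0.1, 1.0, 0.1]],
                                     mol_index=[0, 0, 0])
        water, alcohol = count_occupancy(cfg, PartitionSpec((2, 2, 2)))
        assert water[0] == 1 and water.sum() == 1
        assert alcohol.sum() == 0

    def test_alcohol_straddling_face_counts_in_both_cells(self):
        box = SimulationBox((10.0, 10.0, 10.0))
        # carbons at x = 4.9 and 5.1 straddle the x-midplane of a 2x2x2 grid
        cfg = MolecularConfiguration(
            species=np.array(["alcohol"], dtype=object), box=box,
            elements=np.array(["C", "C", "C", "O", "H"], dtype=object),
            coords=[[4.9, 1, 1], [5.1, 1, 1], [4.8, 1, 1], [4.9, 2.4, 1], [4.9, 3.3, 1]],
            mol_index=[0] * 5)
        water, alcohol = count_occupancy(cfg, PartitionSpec((2, 2, 2)))
        assert alcohol.sum() == 2  # one count in each of two distinct cells

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_nested_loop_oracle(self, seed):
        cfg = gen_random_mixture(MixtureSpec(200, 25.0, seed=seed))
        part = PartitionSpec((5, 5, 5))
        water, alcohol = count_occupancy(cfg, part)
        # independent nested-loop recount
        L = cfg.box.lengths
        cell_len = L / np.array(part.grid_shape)
        w_oracle = np.zeros(part.n_boxes, dtype=int)
        a_oracle = np.zeros(part.n_boxes, dtype=int)
        for m in range(cfg.n_molecules):
            sel = cfg.molecule_atoms(m)
            cells = set()
            for i in sel:
                el = cfg.elements[i]
                pos = np.mod(cfg.coords[i], L)
                idx = tuple(min(int(pos[ax] // cell_len[ax]), part.grid_shape[ax] - 1)
                            for ax in range(3))
                flat = np.ravel_multi_index(idx, part.grid_shape)
                if cfg.species[m] == "water" and el == "O":
                    w_oracle[flat] += 1
                if cfg.species[m] == "alcohol" and el == "C":
                    cells.add(flat)
            for c in cells:
                a_oracle[c] += 1
        assert np.array_equal(water, w_oracle)
        assert np.array_equal(alcohol, a_oracle)

    def test_mixed_periodic_flags_rejected(self):
        box = SimulationBox((10.0, 10.0, 10.0), periodic=(True, True, False))
        cfg = MolecularConfiguration(species=np.array(["water"], dtype=object), box=box,
                                     points=[[1.0, 1.0, 1.0]])
        with pytest.raises(ValueError, match="mixed periodic"):
            count_occupancy(cfg)


class TestDistribution:
    def test_eight_cells_one_occupied(self):
        counts = np.array([1, 0, 0, 0, 0, 0, 0, 0])
        d = build_distribution([counts], species="alcohol")
        assert d.fractions[0] == pytest.approx(0.875)
        assert d.fractions[1] == pytest.approx(0.125)

    def test_fractions_sum_to_one(self):
        for seed in range(3):
            cfg = gen_random_mixture(MixtureSpec(100, 20.0, seed=seed), atomistic=False)
            _, a = count_occupancy(cfg, PartitionSpec((4, 4, 4)))
            d = build_distribution([a], species="alcohol")
            assert d.fractions.sum() == pytest.approx(1.0, abs=1e-12)

    def test_null_zero_occupancy_matches_binomial(self):
        # point-mode null at 1 mol% / 3000 molecules / 1000 cells:
        # N(0) -> (1 - 1/1000)^30 = 0.97043
        d = sample_null_ensemble(MixtureSpec(3000, 1.0, seed=5), PartitionSpec((10, 10, 10)),
                                 n_configs=300, atomistic=False)
        expect = (1 - 1 / 1000) ** 30
        se = np.sqrt(expect * (1 - expect) / d.n_boxes_total)
        assert abs(d.fractions[0] - expect) < 3 * se

    def test_empty_ensemble_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            build_distribution([], species="alcohol")


class TestNonIdeality:
    def test_identical_distributions_zero(self):
        d = _dist([0.5, 0.3, 0.2])
        assert non_ideality(d, d).value == 0.0

    def test_hand_example(self):
        r = non_ideality(_dist([0.5, 0.5]), _dist([0.8, 0.2]))
        assert r.value == pytest.approx(np.sqrt(0.09 + 0.09), abs=1e-15)

    def test_union_support_zero_fill(self):
        r = non_ideality(_dist([0.5, 0.25, 0.25]), _dist([0.5, 0.5]))
        assert r.value == pytest.approx(np.sqrt(0.0625 + 0.0625), abs=1e-15)

    def test_oracle_equivalence_hand_built(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            a = rng.dirichlet(np.ones(rng.integers(2, 8)))
            b = rng.dirichlet(np.ones(rng.integers(2, 8)))
            n = max(len(a), len(b))
            direct = np.sqrt(sum((
                (a[x] if x < len(a) else 0.0) - (b[x] if x < len(b) else 0.0)) ** 2
                for x in range(n)))
            r = non_ideality(_dist(a), _dist(b))
            assert r.value == pytest.approx(direct, abs=1e-12)

    def test_species_mismatch_rejected(self):
        with pytest.raises(ValueError, match="different species"):
            non_ideality(_dist([1.0]), _dist([1.0], species="water"))


class TestTrajectoryPipeline:
    def test_null_against_itself_is_noise_floor(self):
        spec = MixtureSpec(500, 25.0, seed=77)
        traj = gen_mixture_trajectory(spec, 1500, atomistic=False)
        res = trajectory_non_ideality(traj, part=PartitionSpec((5, 5, 5)), seed=101)
        assert res.value < 0.01

    def test_two_null_seeds_below_noise_floor(self):
        part = PartitionSpec((5, 5, 5))
        d1 = sample_null_ensemble(MixtureSpec(500, 10.0, seed=1), part, n_configs=800)
        d2 = sample_null_ensemble(MixtureSpec(500, 10.0, seed=2), part, n_configs=800)
        assert non_ideality(d1, d2).value < 0.01

    def test_monotone_in_clustered_fraction(self):
        values = []
        for frac in (0.0, 0.25, 0.5, 0.75, 1.0):
            spec = MixtureSpec(500, 25.0, seed=5)
            cluster = ClusterSpec(n_clusters=1, cluster_sigma=3.0, clustered_fraction=frac)
            traj = gen_mixture_trajectory(spec, 60, cluster=cluster, atomistic=False)
            res = trajectory_non_ideality(traj, part=PartitionSpec.auto(500), seed=99)
            values.append(res.value)
        assert all(a < b for a, b in zip(values, values[1:]))
        assert values[-1] > 0.4  # extreme single-cluster segregation

    def test_auto_partition_preserves_mean_occupancy(self):
        assert PartitionSpec.auto(3000).grid_shape == (10, 10, 10)
        part = PartitionSpec.auto(500)
        assert 2.0 <= 500 / part.n_boxes <= 4.5
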