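"""RDFs, coordination numbers, and cluster-size distributions."""

import numpy as np
import pytest

import glycopair as gp
from glycopair.frames import FrameSet, minimum_image_distance
from glycopair.structure import (
    RDFResult,
    cluster_size_distribution,
    compute_rdf,
    coordination_number,
)
from glycopair.synthetic import generate_cluster_fixture, generate_ideal_gas_frames


@pytest.fixture(scope="module")
def gas():
    return generate_ideal_gas_frames(500, 4.0, 40, seed=3, species="A")


@pytest.fixture(scope="module")
def gas_rdf(gas):
    return compute_rdf(gas, "A", "A", bin_width=0.02)


class TestRDF:
    def test_ideal_gas_is_unity(self, gas_rdf):
        """Poisson-placed particles: g(r) = 1 away from zero, within noise."""
        m = (gas_rdf.bin_centers >= 0.3) & (gas_rdf.bin_centers <= 0.7)
        assert float(gas_rdf.g[m].mean()) == pytest.approx(1.0, abs=0.05)

    def test_fixed_pair_occupies_single_bin(self):
        coords = np.zeros((1, 2, 3))
        coords[0, 1, 0] = 0.5
        fs = FrameSet(
            coords=coords + 5.0,
            species=("A", "B"),
            mol_ids=np.array([0, 1]),
            box=np.array([20.0] * 3),
        )
        rdf = compute_rdf(fs, "A", "B", bin_width=0.01, r_max=2.0)
        nonzero = np.flatnonzero(rdf.g > 0)
        assert len(nonzero) == 1
        assert rdf.bin_centers[nonzero[0]] == pytest.approx(0.5, abs=0.01)

    def test_pair_count_identity(self, gas, gas_rdf):
        """4 pi rho sum g r^2 dr equals the per-particle pair count inside
        r_max (counting oracle, brute-force distances)."""
        edges = gas_rdf.bin_edges
        shell = (4 * np.pi / 3) * (edges[1:] ** 3 - edges[:-1] ** 3)
        lhs = float(np.sum(gas_rdf.g * shell) * gas_rdf.target_density)
        d = minimum_image_distance(gas.coords[0], gas.coords[0], gas.box)
        iu = np.triu_indices(gas.n_particles, k=1)
        total_pairs = sum(
            2 * np.sum(
                minimum_image_distance(gas.coords[f], gas.coords[f], gas.box)[iu]
                < edges[-1]
            )
            for f in range(gas.n_frames)
        )
        rhs = total_pairs / (gas.n_frames * gas.n_particles)
        assert lhs == pytest.approx(rhs, rel=0.01)
        del d

    def test_r_max_beyond_half_box_rejected(self, gas):
        with pytest.raises(ValueError, match="half"):
            compute_rdf(gas, "A", "A", r_max=2.5)

    def test_empty_selection_rejected(self, gas):
        with pytest.raises(ValueError, match="empty selection"):
            compute_rdf(gas, "A", "Z")

    def test_subsampling_invariance(self, gas):
        """Homogeneous system: RDF from half the frames matches within noise."""
        half = FrameSet(
            coords=gas.coords[::2],
            species=gas.species,
            mol_ids=gas.mol_ids,
            box=gas.box,
        )
        r1 = compute_rdf(gas, "A", "A", bin_width=0.05)
        r2 = compute_rdf(half, "A", "A", bin_width=0.05)
        m = r1.bin_centers > 0.3
        assert np.max(np.abs(r1.g[m] - r2.g[m])) < 0.1


class TestCoordination:
    def test_ideal_gas_closed_form(self, gas_rdf):
        """Running integral to r_cut equals (4 pi / 3) rho r_cut^3 within 3%."""
        cn = coordination_number(gas_rdf, 0.5)
        ideal = (4 * np.pi / 3) * gas_rdf.target_density * 0.5**3
        assert cn == pytest.approx(ideal, rel=0.03)

    def test_zero_g_gives_zero(self):
        rdf = RDFResult(
            bin_centers=np.arange(0.01, 1.0, 0.02),
            g=np.zeros(50),
            pair=("A", "B"),
            target_density=5.0,
        )
        assert coordination_number(rdf, 0.5) == 0.0

    def test_r_cut_outside_grid_rejected(self, gas_rdf):
        with pytest.raises(ValueError, match="outside"):
            coordination_number(gas_rdf, 5.0)

    def test_consistent_with_direct_shell_count(self, thermo):
        """RDF-integrated coordination agrees with direct counting around
        a single center within 5%."""
        rng = np.random.default_rng(12)
        box = np.array([4.0] * 3)
        n_frames, n_gas = 120, 400
        coords = np.empty((n_frames, n_gas + 1, 3))
        coords[:, 0, :] = box / 2
        coords[:, 1:, :] = rng.uniform(0, 4.0, size=(n_frames, n_gas, 3))
        fs = FrameSet(
            coords=coords,
            species=("Ca",) + ("O_S",) * n_gas,
            mol_ids=np.arange(n_gas + 1),
            box=box,
        )
        rdf = compute_rdf(fs, "Ca", "O_S", bin_width=0.02)
        r_cut = 0.335
        cn = coordination_number(rdf, r_cut)
        counts = gp.count_shell_oxygens(fs, gp.ShellConfig(first_shell_cutoff=r_cut))
        assert cn == pytest.approx(counts.mean(), rel=0.05)


class TestClusters:
    def test_constructed_sizes(self):
        fs = generate_cluster_fixture([7, 5, 4], 6.0, 0.3, 1.0)
        dist = cluster_size_distribution(fs, contact_cutoff=0.35, exclude_species=())
        assert dist.probability_of(7) == 1.0
        assert dist.probabilities.sum() == pytest.approx(1.0)

    def test_full_chain(self):
        fs = generate_cluster_fixture([16], 8.0, 0.3, 1.0)
        dist = cluster_size_distribution(fs, contact_cutoff=0.35, exclude_species=())
        assert dist.probability_of(16) == 1.0

    def test_periodic_wrap_merges_components(self):
        """A pair at wrapped distance 0.3 nm across the boundary is one
        cluster of 2 (brute-force minimum-image oracle)."""
        box = np.array([4.0] * 3)
        coords = np.array([[[0.05, 2.0, 2.0], [3.75, 2.0, 2.0]]])
        fs = FrameSet(
            coords=coords, species=("M", "M"), mol_ids=np.array([0, 1]), box=box
        )
        d = minimum_image_distance(coords[0], coords[0], box)
        assert d[0, 1] == pytest.approx(0.3, abs=1e-12)  # oracle
        dist = cluster_size_distribution(fs, contact_cutoff=0.35, exclude_species=())
        assert dist.probability_of(2) == 1.0

    def test_largest_size_monotone_in_cutoff(self):
        fs = generate_cluster_fixture([4, 3, 2], 6.0, 0.3, 1.2)
        sizes = []
        for cutoff in (0.2, 0.35, 1.3, 2.0):
            dist = cluster_size_distribution(
                fs, contact_cutoff=cutoff, exclude_species=()
            )
            sizes.append(dist.mean_size)
        assert sizes == sorted(sizes)

    def test_invariant_under_reordering_and_translation(self):
        fs = generate_cluster_fixture([5, 3], 6.0, 0.3, 1.0)
        rng = np.random.default_rng(4)
        perm = rng.permutation(fs.n_particles)
        shift = np.array([1.7, -2.3, 0.9])
        moved = (fs.coords[:, perm, :] + shift) % fs.box
        fs2 = FrameSet(
            coords=moved,
            species=tuple(fs.species[i] for i in perm),
            mol_ids=fs.mol_ids[perm],
            box=fs.box,
        )
        d1 = cluster_size_distribution(fs, 0.35, exclude_species=())
        d2 = cluster_size_distribution(fs2, 0.35, exclude_species=())
        np.testing.assert_array_equal(d1.probabilities, d2.probabilities)

    def test_cations_excluded_from_connectivity_by_default(self):
        """A Ca2+ bridging two molecules does not merge them unless
        bridging-inclusive mode is requested."""
        box = np.array([6.0] * 3)
        coords = np.array([[[1.0, 3.0, 3.0], [1.3, 3.0, 3.0], [1.6, 3.0, 3.0]]])
        fs = FrameSet(
            coords=coords,
            species=("M", "Ca", "M"),
            mol_ids=np.array([0, 1, 2]),
            box=box,
        )
        separate = cluster_size_distribution(fs, contact_cutoff=0.35)
        assert separate.probability_of(1) == 1.0
        bridged = cluster_size_distribution(fs, contact_cutoff=0.35, exclude_species=())
        assert bridged.probability_of(3) == 1.0

    def test_single_molecule_degenerate_with_warning(self):
        fs = FrameSet(
            coords=np.ones((1, 1, 3)),
            species=("M",),
            mol_ids=np.array([0]),
            box=np.array([4.0] * 3),
        )
        with pytest.warns(UserWarning, match="single molecule"):
            dist = cluster_size_distribution(fs, exclude_species=())
        assert dist.probability_of(1) == 1.0


class TestTrajectoryIngestion:
    def test_from_mdanalysis_universe(self):
        """Real-trajectory ingestion: an MDAnalysis universe converts to a
        FrameSet with nm units and residue-based molecule ids."""
        mda = pytest.importorskip("MDAnalysis")
        u = mda.Universe.empty(
            n_atoms=3, n_residues=2, atom_resindex=[0, 0, 1],
            trajectory=True,
        )
        u.add_TopologyAttr("names", ["O_S", "O_S", "Ca"])
        u.atoms.positions = np.array(
            [[1.0, 1.0, 1.0], [4.0, 1.0, 1.0], [10.0, 10.0, 10.0]]
        )
        u.dimensions = [20.0, 20.0, 20.0, 90.0, 90.0, 90.0]
        fs = FrameSet.from_mdanalysis(u)
        assert fs.n_frames == 1 and fs.n_particles == 3
        np.testing.assert_allclose(fs.box, [2.0, 2.0, 2.0])
        np.testing.assert_allclose(fs.coords[0, 1], [0.4, 0.1, 0.1])
        assert fs.species == ("O_S", "O_S", "Ca")
        np.testing.assert_array_equal(fs.mol_ids, [0, 0, 1])
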