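"""Structural descriptors: RMSD/RMSF/Rg/SASA closed forms and invariances."""

import numpy as np
import pytest

from confens.descriptors import (classify_compactness, distance_geometry,
                                 probability_distribution, radius_of_gyration,
                                 rmsd_series, rmsf_per_residue, sasa)
from confens.ensembles import EnsembleError

from conftest import make_ca_ensemble, random_rotation


# ---------------------------------------------------------------------------
# RMSD


def test_rmsd_reference_is_zero(random_ensemble):
    assert rmsd_series(random_ensemble).values[0] == 0.0


def test_rmsd_uniform_displacement(rng):
    base = rng.normal(size=(6, 3))
    shifted = base + np.array([2.0, 0.0, 0.0])
    ens = make_ca_ensemble(np.stack([base, shifted]))
    assert rmsd_series(ens).values[1] == pytest.approx(2.0, abs=1e-12)


def test_rmsd_matches_bruteforce(rng):
    frames = rng.normal(scale=4, size=(2, 20, 3))
    ens = make_ca_ensemble(frames)
    expect = np.sqrt(np.mean([np.sum((frames[1][a] - frames[0][a]) ** 2)
                              for a in range(20)]))
    assert rmsd_series(ens).values[1] == pytest.approx(expect, rel=1e-12)


def test_rmsd_invariant_under_global_motion(rng, random_ensemble):
    from confens.ensembles import superpose
    vals = rmsd_series(superpose(random_ensemble, 0)).values
    R = random_rotation(rng)
    moved = make_ca_ensemble(random_ensemble.coordinates @ R.T + 11.0)
    vals2 = rmsd_series(superpose(moved, 0)).values
    np.testing.assert_allclose(vals2, vals, atol=1e-9)


# ---------------------------------------------------------------------------
# RMSF


def test_rmsf_static_ensemble_zero(rng):
    frame = rng.normal(size=(5, 3))
    ens = make_ca_ensemble(np.repeat(frame[None], 10, axis=0))
    np.testing.assert_allclose(rmsf_per_residue(ens).values, 0.0, atol=1e-9)


def test_rmsf_gaussian_closed_form(rng):
    # isotropic jitter of σ per coordinate → RMSF = σ√3
    sigma = 0.8
    base = rng.normal(scale=10, size=(4, 3))
    frames = base[None] + rng.normal(scale=sigma, size=(10000, 4, 3))
    prof = rmsf_per_residue(make_ca_ensemble(frames))
    np.testing.assert_allclose(prof.values, sigma * np.sqrt(3), rtol=0.05)


def test_rmsf_two_frame_symmetric(rng):
    base = rng.normal(size=(3, 3))
    moved = base.copy()
    moved[1, 0] += 2.0
    prof = rmsf_per_residue(make_ca_ensemble(np.stack([base, moved])))
    assert prof.values[1] == pytest.approx(1.0, abs=1e-12)
    assert prof.values[0] == pytest.approx(0.0, abs=1e-12)


def test_rmsf_single_frame_warns_flag(rng):
    prof = rmsf_per_residue(make_ca_ensemble(rng.normal(size=(1, 4, 3))))
    assert np.all(prof.values == 0.0)
    assert prof.warning is not None


# ---------------------------------------------------------------------------
# Radius of gyration


@pytest.mark.parametrize("coords,expect", [
    ([[0.0, 0.0, 0.0]], 0.0),
    ([[0, 0, 0], [2, 0, 0]], 1.0),
    ([[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0]], np.sqrt(0.5)),
])
def test_rg_closed_forms(coords, expect):
    ens = make_ca_ensemble(np.asarray(coords, float)[None])
    assert radius_of_gyration(ens).values[0] == pytest.approx(expect, abs=1e-12)


def test_rg_rigid_motion_invariant_and_scaling(rng):
    frames = rng.normal(scale=5, size=(3, 7, 3))
    rg = radius_of_gyration(make_ca_ensemble(frames)).values
    R = random_rotation(rng)
    rg_moved = radius_of_gyration(
        make_ca_ensemble(frames @ R.T + 4.2)).values
    np.testing.assert_allclose(rg_moved, rg, rtol=1e-12)
    rg_scaled = radius_of_gyration(make_ca_ensemble(frames * 3.0)).values
    np.testing.assert_allclose(rg_scaled, 3.0 * rg, rtol=1e-12)


def test_rg_mass_weighted_two_point():
    from confens.ensembles import Topology, ConformationEnsemble
    topo = Topology([1, 2], ["ALA", "ALA"], ["CA", "CA"], ["C", "C"], [0, 1],
                    masses=[1.0, 3.0])
    ens = ConformationEnsemble(topo, np.array([[[0, 0, 0], [4, 0, 0]]], float))
    # com at 3; r² = 9·(1/4) + 1·(3/4) → rg = √3
    assert radius_of_gyration(ens, mass_weighted=True).values[0] == \
        pytest.approx(np.sqrt(3), abs=1e-12)


# ---------------------------------------------------------------------------
# SASA


def test_sasa_isolated_sphere():
    ens = make_ca_ensemble(np.zeros((1, 1, 3)))
    area = sasa(ens, probe_radius=1.4, n_sphere_points=960).values[0]
    assert area == pytest.approx(4 * np.pi * 3.1 ** 2, rel=0.01)


def test_sasa_non_overlapping_doubles():
    far = np.array([[[0, 0, 0], [20.0, 0, 0]]])
    ens = make_ca_ensemble(far)
    single = sasa(make_ca_ensemble(np.zeros((1, 1, 3)))).values[0]
    assert sasa(ens).values[0] == pytest.approx(2 * single, rel=1e-9)


def test_sasa_two_sphere_cap_closed_form():
    # two equal expanded spheres of radius R at distance d: each loses a
    # cap of height h = R - d/2; exposed area 2·(4πR² - 2πRh)
    R = 1.7 + 1.4
    d = 3.0
    ens = make_ca_ensemble(np.array([[[0, 0, 0], [d, 0, 0]]]))
    h = R - d / 2
    expect = 2 * (4 * np.pi * R ** 2 - 2 * np.pi * R * h)
    assert sasa(ens, n_sphere_points=2000).values[0] == \
        pytest.approx(expect, rel=0.02)


def test_sasa_monotone_in_separation():
    seps = [8.0, 6.0, 5.0, 4.0, 3.0, 2.0]
    vals = [sasa(make_ca_ensemble(np.array([[[0, 0, 0], [s, 0, 0]]])),
                 n_sphere_points=960).values[0] for s in seps]
    assert np.all(np.diff(vals) < 1e-9)


def test_sasa_matches_biotite_oracle(rng):
    import biotite.structure as bst
    coords = rng.normal(scale=3.0, size=(6, 3))
    ens = make_ca_ensemble(coords[None])
    mine = sasa(ens, n_sphere_points=1000).values[0]
    arr = bst.AtomArray(6)
    arr.coord = coords
    arr.chain_id = np.full(6, "A")
    arr.res_id = np.arange(1, 7)
    arr.res_name = np.full(6, "ALA")
    arr.atom_name = np.full(6, "CA")
    arr.element = np.full(6, "C")
    ref = bst.sasa(arr, vdw_radii="Single", point_number=1000,
                   probe_radius=1.4).sum()
    assert mine == pytest.approx(ref, rel=0.03)


def test_sasa_unknown_element_errors():
    from confens.ensembles import Topology, ConformationEnsemble
    topo = Topology([1], ["ALA"], ["FE"], ["FE"], [0], masses=[55.8])
    ens = ConformationEnsemble(topo, np.zeros((1, 1, 3)))
    with pytest.raises(EnsembleError, match="FE"):
        sasa(ens)


# ---------------------------------------------------------------------------
# Compactness, distance geometry, histograms


@pytest.mark.parametrize("rg,label", [
    (11.4, "compact"),
    (11.83, "semi-compact"),
    (13.5, "out-of-range"),
    (11.64, "compact"),        # gap value, nearer the compact bin
    (12.26, "loose"),          # gap value, nearer the loose bin
])
def test_compactness_bins(rg, label):
    assert classify_compactness(rg) == label


def test_distance_geometry_345(ca_topology):
    from confens.ensembles import ConformationEnsemble
    coords = np.zeros((2, 5, 3))
    coords[:, 1] = [3, 0, 0]
    coords[:, 2] = [0, 4, 0]
    coords[:, 3] = [10, 10, 10]
    coords[:, 4] = [-5, 2, 1]
    ens = ConformationEnsemble(ca_topology, coords)
    geom = distance_geometry(ens, [689, 690, 691])
    assert geom.distances.shape == (2, 3)
    np.testing.assert_allclose(sorted(geom.distances[0]), [3, 4, 5], atol=1e-12)


def test_distance_geometry_edge_count(ca_topology, rng):
    from confens.ensembles import ConformationEnsemble
    ens = ConformationEnsemble(ca_topology, rng.normal(size=(3, 5, 3)))
    geom = distance_geometry(ens, [689, 690, 691, 692])
    assert len(geom.edges) == 6


def test_distance_geometry_restrained_pair(ca_topology):
    from confens.ensembles import ConformationEnsemble
    coords = np.zeros((4, 5, 3))
    coords[:, 4] = [10.0, 0, 0]
    ens = ConformationEnsemble(ca_topology, coords)
    geom = distance_geometry(ens, [689, 693])
    np.testing.assert_allclose(geom.distances[:, 0], 10.0)


def test_distance_geometry_missing_residue_errors(ca_topology, rng):
    from confens.ensembles import ConformationEnsemble
    ens = ConformationEnsemble(ca_topology, rng.normal(size=(1, 5, 3)))
    with pytest.raises(EnsembleError, match="800"):
        distance_geometry(ens, [689, 800])


def test_histogram_constant_series():
    from confens.descriptors import DescriptorSeries
    h = probability_distribution(DescriptorSeries("x", np.full(50, 3.3)), 0.5)
    assert h.probabilities.max() == 1.0
    assert h.probabilities.sum() == pytest.approx(1.0, abs=1e-12)


def test_histogram_two_point_peaks():
    from confens.descriptors import DescriptorSeries
    vals = np.array([4.0] * 100 + [7.0] * 100)
    h = probability_distribution(DescriptorSeries("x", vals), 0.5)
    peaks = h.peaks()
    assert len(peaks) == 2
    assert all(p == pytest.approx(0.5) for _, p in peaks)


def test_histogram_gaussian_mixture_peak_locations(rng):
    from confens.descriptors import DescriptorSeries
    vals = np.concatenate([rng.normal(4.0, 0.3, 5000),
                           rng.normal(7.0, 0.3, 5000)])
    h = probability_distribution(DescriptorSeries("x", vals), 0.25)
    locs = sorted(loc for loc, _ in h.peaks()[:2])
    assert abs(locs[0] - 4.0) <= 0.25
    assert abs(locs[1] - 7.0) <= 0.25


def test_histogram_sums_to_one(rng):
    from confens.descriptors import DescriptorSeries
    for _ in range(5):
        vals = rng.normal(size=rng.integers(2, 500))
        h = probability_distribution(DescriptorSeries("x", vals), 0.1)
        assert h.probabilities.sum() == pytest.approx(1.0, abs=1e-9)


def test_histogram_bad_width_errors():
    from confens.descriptors import DescriptorSeries
    with pytest.raises(EnsembleError):
        probability_distribution(DescriptorSeries("x", np.ones(3)), 0.0)
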