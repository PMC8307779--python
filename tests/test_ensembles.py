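"""Ensemble containers, multi-model PDB round trips and superposition."""

import numpy as np
import pytest

from confens.ensembles import (ConformationEnsemble, EnsembleError, Topology,
                               concatenate, drop_equilibration, read_ensemble,
                               superpose, write_ensemble)

from conftest import make_ca_ensemble, random_rotation


def quaternion_superpose_rmsd(mobile, reference):
    """Independent superposition oracle: Horn's quaternion method."""
    P = mobile - mobile.mean(axis=0)
    Q = reference - reference.mean(axis=0)
    M = P.T @ Q
    Sxx, Sxy, Sxz = M[0]
    Syx, Syy, Syz = M[1]
    Szx, Szy, Szz = M[2]
    K = np.array([
        [Sxx + Syy + Szz, Syz - Szy, Szx - Sxz, Sxy - Syx],
        [Syz - Szy, Sxx - Syy - Szz, Sxy + Syx, Szx + Sxz],
        [Szx - Sxz, Sxy + Syx, -Sxx + Syy - Szz, Syz + Szy],
        [Sxy - Syx, Szx + Sxz, Syz + Szy, -Sxx - Syy + Szz],
    ])
    lam = np.linalg.eigvalsh(K)[-1]
    msd = (np.sum(P ** 2) + np.sum(Q ** 2) - 2 * lam) / P.shape[0]
    return np.sqrt(max(msd, 0.0))


# ---------------------------------------------------------------------------
# PDB I/O


def write_models(path, frames, mismatch_model=None):
    """Tiny multi-model PDB writer for fixtures (5-residue Cα peptide)."""
    lines = []
    for m, xyz in enumerate(frames, start=1):
        lines.append(f"MODEL     {m:4d}")
        for a, (x, y, z) in enumerate(xyz):
            if mismatch_model == m and a == len(xyz) - 1:
                continue
            lines.append(
                f"ATOM  {a + 1:5d}  CA  ALA A{689 + a:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C")
        lines.append("ENDMDL")
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")


def test_read_counts_models(tmp_path, rng):
    frames = rng.normal(scale=4, size=(3, 5, 3)).round(3)
    write_models(tmp_path / "e.pdb", frames)
    ens = read_ensemble(tmp_path / "e.pdb")
    assert ens.n_frames == 3
    assert ens.n_atoms == 5
    assert ens.topology.residue_numbers[0] == 689
    np.testing.assert_allclose(ens.coordinates, frames, atol=1e-3)


def test_read_single_model(tmp_path, rng):
    write_models(tmp_path / "one.pdb", rng.normal(size=(1, 5, 3)).round(3))
    assert read_ensemble(tmp_path / "one.pdb").n_frames == 1


def test_read_rejects_mismatched_model(tmp_path, rng):
    write_models(tmp_path / "bad.pdb", rng.normal(size=(3, 5, 3)),
                 mismatch_model=2)
    with pytest.raises(EnsembleError, match="model 2"):
        read_ensemble(tmp_path / "bad.pdb")


def test_read_names_bad_line(tmp_path):
    text = ("MODEL        1\n"
            "ATOM      1  CA  ALA A 689       1.000   2.000   x.bad"
            "  1.00  0.00           C\n"
            "ENDMDL\n")
    (tmp_path / "bad.pdb").write_text(text)
    with pytest.raises(EnsembleError, match="line 2"):
        read_ensemble(tmp_path / "bad.pdb")


def test_read_empty_errors(tmp_path):
    (tmp_path / "empty.pdb").write_text("END\n")
    with pytest.raises(EnsembleError, match="no models"):
        read_ensemble(tmp_path / "empty.pdb")


def test_write_read_roundtrip(tmp_path, random_ensemble):
    write_ensemble(random_ensemble, tmp_path / "rt.pdb")
    back = read_ensemble(tmp_path / "rt.pdb")
    # PDB carries 3 decimals
    np.testing.assert_allclose(back.coordinates, random_ensemble.coordinates,
                               atol=5.1e-4)
    assert back.n_frames == random_ensemble.n_frames


# ---------------------------------------------------------------------------
# Superposition


def test_superpose_recovers_rigid_copy(rng):
    base = rng.normal(scale=5, size=(8, 3))
    R = random_rotation(rng)
    moved = base @ R.T + np.array([3.0, -2.0, 7.5])
    ens = make_ca_ensemble(np.stack([base, moved]))
    fitted = superpose(ens, reference_frame=0)
    rms = np.sqrt(np.mean(np.sum(
        (fitted.coordinates[1] - fitted.coordinates[0]) ** 2, axis=1)))
    assert rms <= 1e-10


def test_superpose_idempotent(random_ensemble):
    once = superpose(random_ensemble, 0)
    twice = superpose(once, 0)
    np.testing.assert_allclose(twice.coordinates, once.coordinates, atol=1e-10)


def test_superpose_matches_quaternion_oracle(rng):
    frames = rng.normal(scale=5, size=(6, 10, 3))
    ens = make_ca_ensemble(frames)
    fitted = superpose(ens, 0)
    for f in range(1, 6):
        got = np.sqrt(np.mean(np.sum(
            (fitted.coordinates[f] - frames[0]) ** 2, axis=1)))
        expect = quaternion_superpose_rmsd(frames[f], frames[0])
        assert got == pytest.approx(expect, abs=1e-8)


def test_superpose_preserves_internal_geometry(random_ensemble):
    fitted = superpose(random_ensemble, 0)
    for f in (0, 7, 19):
        before = np.linalg.norm(
            random_ensemble.coordinates[f][:, None]
            - random_ensemble.coordinates[f][None], axis=2)
        after = np.linalg.norm(
            fitted.coordinates[f][:, None] - fitted.coordinates[f][None], axis=2)
        assert np.abs(after - before).max() <= 1e-9


def test_superpose_rejects_degenerate_selection(rng):
    line = np.zeros((2, 4, 3))
    line[:, :, 0] = np.arange(4)
    with pytest.raises(EnsembleError, match="collinear"):
        superpose(make_ca_ensemble(line), 0)
    with pytest.raises(EnsembleError, match=">= 3"):
        from confens.ensembles import AtomSelection
        superpose(make_ca_ensemble(rng.normal(size=(2, 5, 3))), 0,
                  AtomSelection(np.array([0, 1])))


# ---------------------------------------------------------------------------
# Equilibration removal, concatenation


def test_drop_equilibration(random_ensemble):
    kept = drop_equilibration(random_ensemble, 5)
    assert kept.n_frames == 15
    np.testing.assert_array_equal(kept.coordinates,
                                  random_ensemble.coordinates[5:])
    assert drop_equilibration(random_ensemble, 0).n_frames == 20
    with pytest.raises(EnsembleError):
        drop_equilibration(random_ensemble, 20)


def test_concatenate_replicas(rng):
    reps = [make_ca_ensemble(rng.normal(size=(180, 4, 3))) for _ in range(4)]
    merged = concatenate(reps)
    assert merged.n_frames == 720
    single = concatenate([reps[0]])
    np.testing.assert_array_equal(single.coordinates, reps[0].coordinates)


def test_concatenate_mismatch_names_atom(rng):
    a = make_ca_ensemble(rng.normal(size=(3, 4, 3)))
    b = make_ca_ensemble(rng.normal(size=(3, 5, 3)))
    with pytest.raises(EnsembleError, match="mismatch"):
        concatenate([a, b])


def test_topology_invariants():
    with pytest.raises(EnsembleError, match="increasing"):
        Topology([5, 5], ["ALA", "ALA"], ["CA", "CA"], ["C", "C"], [0, 1])
    with pytest.raises(EnsembleError, match="mass"):
        Topology([1, 2], ["ALA", "ALA"], ["CA", "CA"], ["C", "C"], [0, 1],
                 masses=[0.0, 12.0])


def test_strided_subsampling(random_ensemble):
    assert random_ensemble.strided(5).n_frames == 4
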