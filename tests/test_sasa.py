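import math

import numpy as np
import pytest

from astatools import synthetic
from astatools.sasa import (ContactTable, delta_sasa, ensemble_contacts,
                            shrake_rupley, sphere_points)
from astatools.structure import StructureEnsemble

from conftest import make_model

PROBE = 1.4


def brute_force_areas(coords, radii, probe, n_points):
    """Independent O(N^2 * points) reference: golden-angle lattice
    regenerated from the closed form, every point tested against every
    other atom."""
    n = len(coords)
    golden = math.pi * (3.0 - math.sqrt(5.0))
    pts = []
    for k in range(n_points):
        z = 1.0 - (2.0 * k + 1.0) / n_points
        rho = math.sqrt(max(1.0 - z * z, 0.0))
        pts.append((rho * math.cos(k * golden), rho * math.sin(k * golden),
                    z))
    pts = np.asarray(pts)
    areas = np.zeros(n)
    for i in range(n):
        ri = radii[i] + probe
        test = coords[i] + ri * pts
        free = np.ones(n_points, dtype=bool)
        for j in range(n):
            if j == i:
                continue
            rj = radii[j] + probe
            free &= np.sum((test - coords[j]) ** 2, axis=1) >= rj * rj
        areas[i] = free.mean() * 4.0 * math.pi * ri * ri
    return areas


def test_isolated_atom_matches_closed_form_exactly():
    model = make_model([[0.0, 0.0, 0.0]], radius=1.7)
    result = shrake_rupley(model, probe=PROBE, n_points=960)
    expected = 4.0 * math.pi * (1.7 + PROBE) ** 2  # ≈ 120.76 Å²
    assert result.total_area == pytest.approx(expected, rel=1e-12)
    assert result.total_area == pytest.approx(120.76, abs=0.01)


@pytest.mark.parametrize("n_points", [60, 240, 960])
def test_two_distant_atoms_keep_isolated_area(n_points):
    model = make_model([[0.0, 0.0, 0.0], [100.0, 0.0, 0.0]])
    result = shrake_rupley(model, probe=PROBE, n_points=n_points)
    expected = 4.0 * math.pi * (1.7 + PROBE) ** 2
    np.testing.assert_allclose(result.per_atom_area, expected, rtol=1e-12)


def test_fully_caged_atom_has_zero_area():
    # occluder shell: 6 axis + 8 diagonal directions at 2.0 Å covers every
    # direction within the occlusion angle of a carbon probe sphere
    dirs = [v for v in
            ([1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1],
             [0, 0, -1])]
    dirs += [[sx / math.sqrt(3), sy / math.sqrt(3), sz / math.sqrt(3)]
             for sx in (-1, 1) for sy in (-1, 1) for sz in (-1, 1)]
    coords = np.vstack([[0.0, 0.0, 0.0], 2.0 * np.asarray(dirs)])
    model = make_model(coords)
    result = shrake_rupley(model, probe=PROBE, n_points=960)
    assert result.per_atom_area[0] == 0.0
    oracle = brute_force_areas(coords, np.full(len(coords), 1.7), PROBE, 960)
    assert oracle[0] == 0.0


@pytest.mark.parametrize("seed,n_atoms", [(0, 12), (1, 30), (2, 50)])
def test_equivalence_with_brute_force_reference(seed, n_atoms):
    """Neighbor-search pruning must not change a single point decision."""
    rng = np.random.default_rng(seed)
    coords = rng.uniform(-6.0, 6.0, (n_atoms, 3))
    radii = rng.uniform(1.2, 2.0, n_atoms)
    model = make_model(coords, radius=radii)
    result = shrake_rupley(model, probe=PROBE, n_points=240)
    oracle = brute_force_areas(coords, radii, PROBE, 240)
    np.testing.assert_allclose(result.per_atom_area, oracle, atol=1e-9)


def test_adding_occluder_never_increases_area():
    rng = np.random.default_rng(7)
    coords = rng.uniform(-4.0, 4.0, (15, 3))
    base = shrake_rupley(make_model(coords), probe=PROBE, n_points=240)
    for trial in range(5):
        extra = np.vstack([coords, rng.uniform(-4.0, 4.0, (1, 3))])
        more = shrake_rupley(make_model(extra), probe=PROBE, n_points=240)
        assert np.all(more.per_atom_area[:15] <= base.per_atom_area + 1e-9)


def test_per_residue_areas_sum_to_per_atom_total(tunnel_single):
    _, ensemble, _ = tunnel_single
    result = shrake_rupley(ensemble[0], probe=PROBE, n_points=240)
    assert sum(result.per_residue_area.values()) == pytest.approx(
        result.total_area)


def test_lattice_needs_ten_points_minimum():
    with pytest.raises(ValueError):
        sphere_points(5)
    model = make_model([[0.0, 0.0, 0.0]])
    with pytest.raises(ValueError):
        shrake_rupley(model, probe=PROBE, n_points=9)


def test_distant_ligand_produces_zero_delta_sasa(tunnel_single):
    _, ensemble, _ = tunnel_single
    model = ensemble[0]
    import dataclasses
    shifted = [dataclasses.replace(a, position=a.position + 100.0)
               if a.is_hetero else a for a in model]
    far = dataclasses.replace(model, atoms=shifted)
    deltas = delta_sasa(far, synthetic.LIGAND_SELECTION, PROBE, 240)
    assert all(v == 0.0 for v in deltas.values())


def test_planted_contacts_recovered_exactly_single_model(tunnel_single):
    _, ensemble, contacts = tunnel_single
    table = ensemble_contacts(ensemble, synthetic.LIGAND_SELECTION)
    found = set(table.contact_residue_numbers)
    planted = set(contacts)
    assert found == planted  # precision = recall = 1.0


def test_planted_contacts_survive_ensemble_jitter(tunnel_ensemble):
    _, ensemble, contacts = tunnel_ensemble
    table = ensemble_contacts(ensemble, synthetic.LIGAND_SELECTION)
    assert set(table.contact_residue_numbers) == set(contacts)
    assert table.ensemble_size == 10


def test_single_model_mean_equals_model_delta(tunnel_single):
    _, ensemble, _ = tunnel_single
    table = ensemble_contacts(ensemble, synthetic.LIGAND_SELECTION)
    deltas = delta_sasa(ensemble[0], synthetic.LIGAND_SELECTION)
    for record in table.records:
        assert record.delta_sasa_aggregate == pytest.approx(
            deltas[record.residue_key])


def test_infinite_cutoff_yields_no_contacts(tunnel_single):
    _, ensemble, _ = tunnel_single
    table = ensemble_contacts(ensemble, synthetic.LIGAND_SELECTION,
                              cutoff=float("inf"), n_points=60)
    assert table.contacts == []


def test_heterogeneous_topology_rejected(tunnel_single):
    _, ensemble, _ = tunnel_single
    import dataclasses
    truncated = dataclasses.replace(ensemble[0],
                                    atoms=ensemble[0].atoms[:-1])
    bad = StructureEnsemble([ensemble[0], truncated])
    with pytest.raises(ValueError, match="topology"):
        ensemble_contacts(bad, synthetic.LIGAND_SELECTION)


def test_cross_check_against_biotite_shrake_rupley():
    """Independent library implementation agrees on a random cluster."""
    biotite_structure = pytest.importorskip("biotite.structure")
    rng = np.random.default_rng(3)
    coords = rng.uniform(-5.0, 5.0, (20, 3))
    model = make_model(coords, radius=1.7)
    ours = shrake_rupley(model, probe=PROBE, n_points=960)
    arr = biotite_structure.AtomArray(20)
    arr.coord = coords.astype(np.float32)
    arr.set_annotation("element", np.array(["C"] * 20))
    theirs = biotite_structure.sasa(arr, probe_radius=PROBE,
                                    vdw_radii=np.full(20, 1.7),
                                    point_number=1000)
    np.testing.assert_allclose(ours.per_atom_area, theirs, rtol=0.05,
                               atol=1.0)
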