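import numpy as np
import pytest

from allomap import diffmap, synthetic_data


@pytest.fixture(scope="session")
def toy_model():
    return synthetic_data.make_toy_structure(10, seed=1)


@pytest.fixture(scope="session")
def toy_reflections(toy_model):
    return synthetic_data.simulate_structure_factors(toy_model, d_min=2.0)


@pytest.fixture(scope="session")
def perturbed_pair():
    """(wt_model, mut_model) with residue 4's CB displaced by 1.5 A."""
    wt = synthetic_data.make_toy_structure(10, seed=1)
    mut = synthetic_data.perturb_structure(wt, {4}, displacement=1.5, seed=3)
    return wt, mut


@pytest.fixture(scope="session")
def noisy_difference_map(perturbed_pair):
    """Weighted difference map for the perturbed pair at 5% amplitude noise."""
    wt, mut = perturbed_pair
    f_wt = synthetic_data.add_measurement_noise(
        synthetic_data.simulate_structure_factors(wt, 2.0), 0.05, seed=11
    )
    f_mut = synthetic_data.add_measurement_noise(
        synthetic_data.simulate_structure_factors(mut, 2.0), 0.05, seed=12
    )
    scaled = diffmap.scale_to_reference(f_mut, f_wt)
    coeffs = diffmap.phase_from_model(
        diffmap.weighted_differences(scaled.reflections, f_wt), wt
    )
    return diffmap.synthesize_map(coeffs, grid_spacing=0.5)


def brute_force_iaddat(density_map, model, threshold=0.04, radius=1.5):
    """Exhaustive grid-scan oracle for the per-residue density score.

    Walks every grid point in scan order, computes minimum-image distances
    to every protein heavy atom, and accumulates |density| onto the
    residue of the single nearest atom within the radius. Deliberately a
    plain loop: the optimized implementation must match it exactly.
    """
    atoms = [a for a in model.atoms if not a.is_hydrogen and not a.is_water]
    atoms.sort(key=lambda a: (a.chain_id, a.residue_index, a.atom_id))
    orth = model.orth_matrix
    inv = np.linalg.inv(orth)
    atom_frac = np.array([inv @ a.xyz for a in atoms])
    atom_frac -= np.floor(atom_frac)
    residues = model.residue_indices()
    res_pos = {r: i for i, r in enumerate(residues)}
    atom_slot = np.array([res_pos[a.residue_index] for a in atoms])
    n_heavy = np.zeros(len(residues))
    for a in atoms:
        n_heavy[res_pos[a.residue_index]] += 1

    vals = density_map.values
    shape = np.array(vals.shape, dtype=float)
    sums = np.zeros(len(residues))
    r2 = radius * radius
    nx, ny, nz = vals.shape
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                v = vals[i, j, k]
                if abs(v) <= threshold:
                    continue
                fp = np.array([i, j, k]) / shape
                delta = atom_frac - fp
                delta -= np.round(delta)
                cart = delta @ orth.T
                d2 = (cart**2).sum(axis=-1)
                nearest = np.argmin(d2)
                if d2[nearest] <= r2:
                    sums[atom_slot[nearest]] += abs(v)
    return np.array(residues), sums / n_heavy
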