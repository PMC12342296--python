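"""Shared fixtures: small simulated datasets and hand-built cells.

Session scope amortizes intensity calibration (cached per configuration)
across the suite; every fixture is seeded, so the suite is deterministic.
"""

import numpy as np
import pytest

import meioco as m


def make_sc(cell_id, length, foci, cen=0.0, morphology="acrocentric", rank=None):
    return m.SCObservation(
        cell_id=cell_id,
        length_um=length,
        centromere_um=cen,
        morphology=morphology,
        foci_um=sorted(foci),
        sc_rank=rank,
    )


def make_cell(cell_id, sc_specs, temperature=28.0, animal="a1", stage="pachytene"):
    """sc_specs: list of (length, foci, cen, morphology) tuples."""
    scs = [
        make_sc(cell_id, L, foci, cen, morph, rank=i + 1)
        for i, (L, foci, cen, morph) in enumerate(sc_specs)
    ]
    return m.CellRecord(cell_id=cell_id, animal_id=animal, temperature_C=temperature, stage=stage, scs=scs)


def full_cell(cell_id, foci_per_sc=1, temperature=28.0, animal="a1"):
    """A 17-SC cell on the reference profile with k evenly placed foci per SC."""
    specs = []
    for i, L in enumerate(m.DEFAULT_SC_PROFILE_UM):
        morph = "metacentric" if (i + 1) in (1, 4) else "acrocentric"
        cen = 0.45 * L if morph == "metacentric" else 0.0
        foci = [L * (j + 1) / (foci_per_sc + 1) for j in range(foci_per_sc)]
        specs.append((L, foci, cen, morph))
    return make_cell(cell_id, specs, temperature=temperature, animal=animal)


@pytest.fixture(scope="session")
def ds28():
    """Ranked 28 °C-preset dataset, 40 cells (the reference-condition size)."""
    ds = m.simulate_dataset(m.condition_preset(28.0, n_cells=40, seed=101))
    ranked, excluded = m.rank_dataset(ds)
    assert not excluded
    return ranked


@pytest.fixture(scope="session")
def ds_poisson():
    """No-interference, no-conditioning dataset: ν=1, fixed intensity."""
    cfg = m.SimConfig(
        nu=1.0,
        intensity_per_um=0.0197,
        target_mean_foci_per_cell=None,
        obligate_co=False,
        centromere_suppression_p=0.0,
        length_cv=0.0,
        n_cells=150,
        seed=202,
    )
    ranked, _ = m.rank_dataset(m.simulate_dataset(cfg))
    return ranked


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(7)
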