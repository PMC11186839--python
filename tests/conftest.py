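import numpy as np
import pytest

from ctmm import CellLevelGene, SimulationConfig, simulate_ctp


def make_cells(spec: dict, name: str = "g") -> CellLevelGene:
    """Build a CellLevelGene from {(individual, cell_type): values}."""
    values, ind, ct = [], [], []
    for (i, c), vals in spec.items():
        vals = np.asarray(vals, dtype=float)
        values.append(vals)
        ind += [i] * len(vals)
        ct += [c] * len(vals)
    return CellLevelGene(values=np.concatenate(values),
                         individual=np.array(ind), cell_type=np.array(ct),
                         name=name)


@pytest.fixture
def cells_factory():
    return make_cells


@pytest.fixture
def random_cells():
    """A moderately sized synthetic gene: 12 individuals x 3 cell types,
    20-40 cells per pair, Gaussian cell-level expression."""
    rng = np.random.default_rng(42)
    spec = {}
    for i in range(12):
        for c in range(3):
            n = int(rng.integers(20, 41))
            spec[(f"i{i:02d}", f"ct{c}")] = rng.normal(c + 0.5 * (i % 3), 1.0, n)
    return make_cells(spec, name="random_gene")


@pytest.fixture
def small_free_pb():
    """Complete CTP pseudobulk simulated under the Free model (N=30, C=3)."""
    cfg = SimulationConfig(n_individuals=30, n_cell_types=3,
                           structure="free", seed=7)
    pb, truth = simulate_ctp(cfg, 0)
    return pb, truth


@pytest.fixture
def hom_pb():
    """Complete CTP pseudobulk simulated under the Hom model (N=40, C=4)."""
    cfg = SimulationConfig(n_individuals=40, n_cell_types=4,
                           structure="hom", seed=19)
    pb, truth = simulate_ctp(cfg, 0)
    return pb, truth
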