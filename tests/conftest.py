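import numpy as np
import pytest

from fosjump import simulate as sim
from fosjump.vector import build_vector_map


@pytest.fixture(scope="session")
def phz_vector():
    return build_vector_map("pHZAUFOS3")


@pytest.fixture(scope="session")
def pcc_vector():
    return build_vector_map("pcc2FOS")


@pytest.fixture(scope="session")
def genome_1mb():
    return sim.make_genome(1, [1_000_000], 0.4, seed=101)


@pytest.fixture(scope="session")
def tags(phz_vector):
    return {
        "VES1": phz_vector.ves1_seq,
        "VES2": phz_vector.ves2_seq,
        "AmpTag": sim.amp_tag_sequence(),
    }


@pytest.fixture(scope="session")
def errorfree_library(genome_1mb, phz_vector):
    """Mechanical-route error-free library at 10x physical coverage."""
    params = sim.SimulationParams(read_accuracy=1.0, coverage=10.0)
    rng = np.random.default_rng(202)
    clones = sim.simulate_fosmid_library(genome_1mb, params, rng)
    frags = []
    for c in clones:
        frags.extend(sim.shear_and_select(sim.clone_molecule(c, genome_1mb, phz_vector), params, rng))
    mols = sim.build_pe_molecules(frags, {c.id: c for c in clones}, genome_1mb, phz_vector, params, rng)
    reads, truth = sim.simulate_reads(mols, phz_vector, params, rng)
    return {
        "params": params,
        "clones": clones,
        "fragments": frags,
        "molecules": mols,
        "reads": reads,
        "truth": truth,
    }
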