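import pytest

from ytraffic import io
from ytraffic.simdata import GenomeSpec, ReadSimConfig, simulate_genome, simulate_reads


@pytest.fixture(scope="session")
def toy_genome():
    """Small labeled genome with shared repeats, plus error-free 10x sexed reads."""
    spec = GenomeSpec(
        n_autosomal_scaffolds=3,
        n_y_scaffolds=2,
        scaffold_length_bp=12_000,
        repeat_fraction=0.15,
        gc=0.45,
        seed=101,
    )
    scaffolds, truth = simulate_genome(spec)
    male, _ = simulate_reads(scaffolds, truth, ReadSimConfig(sex="male", depth=10, seed=102))
    female, _ = simulate_reads(scaffolds, truth, ReadSimConfig(sex="female", depth=10, seed=103))
    return scaffolds, truth, male, female


@pytest.fixture()
def caterpillar_tree():
    """Focal species plus five progressively more distant outgroups."""
    return io.tree_from_newick(
        "(((((focal:1,o1:1):1,o2:2):1,o3:3):1,o4:4):1,o5:5);"
    )


@pytest.fixture()
def balanced_tree():
    return io.tree_from_newick("((A:1.0,B:1.0):1.0,(C:1.0,D:1.0):1.0);")
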