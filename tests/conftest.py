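import numpy as np
import pytest

from bridgethemes import io as btio
from bridgethemes.synthetic import PlantConfig, generate_benchmark


@pytest.fixture(scope="session")
def small_benchmark(tmp_path_factory):
    """A compact planted benchmark shared by the detection-level tests:
    6 X-groups x 2 domains, 4 themes, substitution rate 0.2."""
    out = tmp_path_factory.mktemp("bench")
    config = PlantConfig(n_xgroups=6, domains_per_group=2, n_themes=4,
                         theme_substitution_rate=0.2, ligand_fraction=1.0,
                         seed=7)
    paths = generate_benchmark(config, out)
    return config, paths


@pytest.fixture(scope="session")
def small_benchmark_data(small_benchmark):
    config, paths = small_benchmark
    return {
        "config": config,
        "paths": paths,
        "fasta": dict(btio.read_fasta(paths.fasta)),
        "classification": btio.read_classification(paths.classification),
        "hits": btio.read_hits(paths.hits),
        "truth": btio.read_truth(paths.truth),
    }


TOY_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  CB  ALA A   1       2.000   1.400   0.000  1.00  0.00           C
ATOM      4  CA AGLY A   2       4.100   1.000   0.500  0.60  0.00           C
ATOM      5  CA BGLY A   2       4.900   1.200   0.700  0.40  0.00           C
ATOM      6  CA  CYS A   3       7.300   2.000   1.000  1.00  0.00           C
ATOM      7  SG  CYS A   3       8.000   3.500   1.200  1.00  0.00           S
HETATM    8 ZN    ZN A 101       2.500   2.500   0.500  1.00  0.00          ZN
END
"""


@pytest.fixture()
def toy_pdb(tmp_path):
    path = tmp_path / "toy.pdb"
    path.write_text(TOY_PDB)
    return path


@pytest.fixture(scope="session")
def rigid_transform_rng():
    return np.random.default_rng(1234)
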