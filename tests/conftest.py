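import pytest

from famevol.codon_alignment import Alignment
from famevol.evodist import distance_matrix
from famevol.simulate import SimulationConfig, emit_inputs, simulate_family


@pytest.fixture(scope="session")
def family():
    """Default synthetic family (5 orthologous + 5 complex groups)."""
    return simulate_family(SimulationConfig(seed=7))


@pytest.fixture(scope="session")
def family_dir(family, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("family")
    emit_inputs(family, outdir)
    return outdir


@pytest.fixture(scope="session")
def codon_aln(family) -> Alignment:
    return family.true_alignment()


@pytest.fixture(scope="session")
def d_matrix(family, codon_aln):
    return distance_matrix(codon_aln, "d")
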