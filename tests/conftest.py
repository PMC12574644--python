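import pytest

from phageforge import DesignSpec, design

CG27_SPEC = DesignSpec(length_nt=1415, cg_fraction=0.27, seed=1)
CPG40_SPEC = DesignSpec(length_nt=1415, cg_fraction=0.27,
                        hexamer_fraction=0.4, seed=1)


@pytest.fixture(scope="session")
def cg27_result():
    """Full CG-series design at the reference conditions (1415 nt, 27% CG)."""
    return design(CG27_SPEC)


@pytest.fixture(scope="session")
def cpg40_result():
    """CG27 conditions plus conversion of 40% of CG dimers to CpG hexamers."""
    return design(CPG40_SPEC)
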