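import numpy as np
import pytest

from proteox.chem import apply_modification, parse_peptide
from proteox.synth import substrate_peak_table


@pytest.fixture(scope="session")
def substrate():
    """Succinyl-Ala-His-Pro-Phe-p-nitroanilide, the phosphatase substrate."""
    return parse_peptide("Suc-AHPF-pNA")


@pytest.fixture(scope="session")
def phospho_substrate(substrate):
    return apply_modification(substrate, "phospho", 2)


@pytest.fixture(scope="session")
def assay_peaks():
    """Six-peak table of the infusion assay (691/713/729 and 771/793/809)."""
    return substrate_peak_table()


@pytest.fixture
def rng():
    return np.random.default_rng(42)
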