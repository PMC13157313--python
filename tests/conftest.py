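import pytest

from vetamu import ConversionTable
from vetamu.reference import write_reference_bundle


@pytest.fixture(scope="session")
def conv_table() -> ConversionTable:
    """Conversion table with a known benzylpenicillin factor (0.0006 mg/IU)."""
    return ConversionTable(
        iu_factors={"benzylpenicillin": 0.0006, "streptomycin": 0.00125},
        dddvet={("oxytetracycline", "cattle", "oral"): 20.0},
    )


@pytest.fixture(scope="session")
def reference_bundle(tmp_path_factory):
    """The bundled reference survey materialized as pipeline input files."""
    d = tmp_path_factory.mktemp("refbundle")
    return write_reference_bundle(d)
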