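import numpy as np
import pytest

from kinobarseq import BarcodeCatalog, DeletionStrain, SampleSheet
from kinobarseq.simulate import _codes_to_str, _random_distinct_barcodes


@pytest.fixture
def toy_catalog() -> BarcodeCatalog:
    """Ten strains with random, well-separated (Hamming >= 3) UPTAGs."""
    rng = np.random.default_rng(42)
    codes = _random_distinct_barcodes(rng, 10, 20, 3)
    return BarcodeCatalog(
        DeletionStrain(f"s{i:02d}", f"g{i:02d}", _codes_to_str(codes[i]))
        for i in range(10)
    )


@pytest.fixture
def toy_sheet() -> SampleSheet:
    return SampleSheet(
        {
            "KIN_A": ("AACCTT", "TTGGAA"),
            "KIN_B": ("GGTTAA", "CCAATT"),
            "KIN_C": ("ACACAC", "GTGTGT"),
        }
    )
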