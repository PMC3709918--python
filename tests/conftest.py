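import numpy as np
import pandas as pd
import pytest

from aflpscan.io_model import BandMatrix, LocusMeta, SampleMap


@pytest.fixture
def toy_dataset():
    """4 individuals x 3 loci with one missing entry, two populations."""
    pheno = np.array(
        [
            [1.0, 0.0, 1.0],
            [0.0, 1.0, np.nan],
            [1.0, 1.0, 0.0],
            [1.0, 0.0, 1.0],
        ]
    )
    band = BandMatrix(pheno, ["s1", "s2", "s3", "s4"], ["L1", "L2", "L3"])
    smap = SampleMap(
        pd.DataFrame(
            {
                "population": ["A", "A", "B", "B"],
                "host_type": ["maize", "maize", "dicot", "dicot"],
                "country": ["FR", "FR", "FR", "FR"],
            },
            index=pd.Index(["s1", "s2", "s3", "s4"], name="sample_id"),
        )
    )
    meta = LocusMeta(
        pd.DataFrame(
            {"fragment_size": [100, 200, 300]},
            index=pd.Index(["L1", "L2", "L3"], name="locus_id"),
        )
    )
    return band, smap, meta


def make_sample_map(pops: dict[str, tuple[str, str, int]]) -> SampleMap:
    """pops: name -> (host_type, country, n individuals)."""
    rows = []
    for name, (host, country, n) in pops.items():
        for i in range(n):
            rows.append(
                {
                    "sample_id": f"{name}_{i}",
                    "population": name,
                    "host_type": host,
                    "country": country,
                }
            )
    return SampleMap(pd.DataFrame(rows).set_index("sample_id"))
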