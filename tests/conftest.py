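import numpy as np
import pytest

from coreset_gbs.io_formats import MISSING, GenotypeMatrix, SiteRecord
from coreset_gbs.synthetic_data import PanelSimConfig, simulate_panel


def make_geno(dosages, sample_ids=None, chrom="PG_1", infos=None, alleles=None):
    """Build a GenotypeMatrix from a plain list-of-lists dosage table."""
    d = np.asarray(dosages, dtype=np.int8)
    n, m = d.shape
    sample_ids = sample_ids or [f"s{i+1}" for i in range(n)]
    sites = []
    for j in range(m):
        ref, alt = ("A", "C") if alleles is None else alleles[j]
        info = infos[j] if infos else {}
        sites.append(SiteRecord(chrom, 100 * (j + 1), ref, alt, dict(info)))
    return GenotypeMatrix(sample_ids, sites, d)


@pytest.fixture
def tiny_geno():
    # 4 samples x 5 sites, one missing call, hand-countable
    return make_geno(
        [
            [0, 0, 1, 2, 0],
            [0, 1, 1, 2, 0],
            [1, 1, 0, 2, 0],
            [2, MISSING, 1, 2, 0],
        ]
    )


@pytest.fixture(scope="session")
def small_panel():
    """Deterministic structured panel shared across tests (80 x 600)."""
    cfg = PanelSimConfig(n_samples=80, n_sites=600, n_subpops=3, fst=0.10,
                         missing_rate=0.02, seed=11)
    geno, truth = simulate_panel(cfg)
    return geno, truth
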