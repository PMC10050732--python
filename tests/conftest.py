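import numpy as np
import pytest

from mrkit.datasets import load_cortisol_instruments
from mrkit.gwas_io import HarmonizedDataset, LdMatrix


def make_dataset(bx, sx, by, sy, ld_r=None, eaf=None) -> HarmonizedDataset:
    """Build a HarmonizedDataset directly from parallel arrays (test shortcut)."""
    bx = np.asarray(bx, dtype=float)
    k = bx.size
    ids = tuple(f"rs{i + 1}" for i in range(k))
    ld = LdMatrix(ids, np.asarray(ld_r, dtype=float)) if ld_r is not None else LdMatrix.identity(ids)
    return HarmonizedDataset(
        snp_ids=ids,
        effect_alleles=("A",) * k,
        other_alleles=("G",) * k,
        beta_exposure=bx,
        se_exposure=np.asarray(sx, dtype=float),
        beta_outcome=np.asarray(by, dtype=float),
        se_outcome=np.asarray(sy, dtype=float),
        eaf=np.asarray(eaf, dtype=float) if eaf is not None else np.full(k, 0.3),
        ld=ld,
    )


@pytest.fixture(scope="session")
def cortisol_records():
    return load_cortisol_instruments()
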