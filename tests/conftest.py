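import warnings
from pathlib import Path

import numpy as np
import pytest
import scipy.sparse as sp

from salsa import CountStack

warnings.filterwarnings("ignore", category=UserWarning)

CACHE = Path(__file__).resolve().parent.parent / "scratch" / "pbmc3k"
PBMC_URL = ("https://s3-us-west-2.amazonaws.com/10x.files/samples/cell/pbmc3k/"
            "pbmc3k_filtered_gene_bc_matrices.tar.gz")


def toy_stack(entries, n_genes, n_barcodes):
    """CountStack from explicit (gene, barcode, umi) triplets."""
    return CountStack.from_entries(
        entries,
        gene_ids=[f"G{i}" for i in range(n_genes)],
        barcode_ids=[f"B{i}" for i in range(n_barcodes)],
    )


def random_stack(rng, n_genes=20, n_barcodes=15, density=0.3, max_umi=6):
    mask = rng.random((n_genes, n_barcodes)) < density
    counts = rng.integers(1, max_umi + 1, size=(n_genes, n_barcodes)) * mask
    return CountStack(
        sp.csr_matrix(counts),
        [f"G{i}" for i in range(n_genes)],
        [f"B{i}" for i in range(n_barcodes)],
    ), counts


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def pbmc3k_matrix_dir():
    """Locate (or fetch) the PBMC 3K filtered matrix; fail the test if unavailable."""
    target = CACHE / "filtered_gene_bc_matrices" / "hg19"
    if (target / "matrix.mtx").exists():
        return target
    import io
    import tarfile
    import urllib.request

    CACHE.mkdir(parents=True, exist_ok=True)
    try:
        with urllib.request.urlopen(PBMC_URL, timeout=30) as resp:
            payload = resp.read()
    except Exception as exc:  # noqa: BLE001
        pytest.fail(f"PBMC 3K matrix not cached and could not be downloaded: {exc}")
    with tarfile.open(fileobj=io.BytesIO(payload), mode="r:gz") as tar:
        tar.extractall(CACHE, filter="data")
    if not (target / "matrix.mtx").exists():
        pytest.fail("PBMC 3K archive did not contain the expected matrix layout")
    return target
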