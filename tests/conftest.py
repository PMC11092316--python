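import numpy as np
import pandas as pd
import pytest

from cnacall.genome_model import make_bin_grid
from cnacall.synthetic_data import scaled_autosome_sizes, synthetic_cytoband_map


@pytest.fixture(scope="session")
def small_sizes():
    """1/10-scale autosome sizes: ~580 bins at 500 kb."""
    return scaled_autosome_sizes(10)


@pytest.fixture(scope="session")
def small_grid(small_sizes):
    return make_bin_grid(small_sizes)


@pytest.fixture(scope="session")
def small_cyto(small_sizes):
    return synthetic_cytoband_map(small_sizes)


@pytest.fixture()
def toy_grid():
    """Hand-built 2-chromosome grid: 10 + 6 bins of 1 kb, one masked bin."""
    rows = []
    for chrom, n in (("1", 10), ("2", 6)):
        for i in range(n):
            rows.append((chrom, i * 1000, (i + 1) * 1000, 0.5, 1.0, True))
    bins = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "gc", "mappability", "usable"]
    )
    bins.loc[3, ["mappability", "usable"]] = [0.2, False]
    return make_bin_grid(
        {"1": 10_000, "2": 6_000},
        bin_size=1000,
        annotations=bins[["gc", "mappability"]].assign(
            mappability=bins["mappability"]
        ),
    )


@pytest.fixture()
def toy_cytoband_file(tmp_path):
    """UCSC-dialect cytoband file for a 3-band toy chromosome."""
    lines = [
        "chr1\t0\t4000\tp12\tgpos50",
        "chr1\t4000\t6000\tp11\tacen",
        "chr1\t6000\t10000\tq12\tgneg",
        "chr2\t0\t2000\tp11\tacen",
        "chr2\t2000\t6000\tq11\tgneg",
    ]
    path = tmp_path / "cytoBand.txt"
    path.write_text("\n".join(lines) + "\n")
    return path


def assert_frames_equal(a, b, **kw):
    pd.testing.assert_frame_equal(a, b, **kw)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)
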