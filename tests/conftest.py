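import os

import numpy as np
import pytest
from hypothesis import settings

from cnvselscan.core import SamplePanel, SVRecord

settings.register_profile("fixed", derandomize=True)
settings.load_profile("fixed")

DATA_DIR = os.path.join(os.path.dirname(__file__), "data")


def make_record(
    rid="v1",
    chrom="chr1",
    pos=1000,
    svlen=None,
    end=None,
    svtype="DEL",
    genotypes=(0, 1, 2, 0),
):
    g = np.asarray(genotypes, dtype=np.int8)
    if end is None and svlen is None:
        svlen = -1000
    if end is None:
        end = pos + abs(svlen) - 1 if svtype != "INS" else pos
    if svlen is None:
        svlen = -(end - pos + 1) if svtype == "DEL" else end - pos + 1
    return SVRecord(rid, chrom, pos, end, svtype, svlen, g)


@pytest.fixture
def small_panel():
    samples = [f"HL{i:02d}" for i in range(1, 6)] + [
        f"LL{i:02d}" for i in range(1, 6)
    ]
    return SamplePanel(samples, {s: s[:2] for s in samples})


@pytest.fixture
def panel_30():
    samples = [f"HL{i:02d}" for i in range(1, 16)] + [
        f"LL{i:02d}" for i in range(1, 16)
    ]
    return SamplePanel(samples, {s: s[:2] for s in samples})


@pytest.fixture
def toy_qc_vcf():
    return os.path.join(DATA_DIR, "toy_qc.vcf")


@pytest.fixture
def toy_panel_path():
    return os.path.join(DATA_DIR, "toy_panel.tsv")
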