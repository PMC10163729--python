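import numpy as np
import pytest

from umicollide import ReadRecord, make_panel


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_panel():
    """11 loci (7 SNV, 2 del, 2 ins) over 4 kbp."""
    return make_panel(7, 2, 2, span_bp=4000)


def make_read(
    read_id,
    strand,
    umi=("AAAA", "CCCC"),
    key=("panel1", 100, 285),
    calls=None,
    molecule_id=0,
):
    contig, start, end = key
    return ReadRecord(
        read_id=read_id,
        contig=contig,
        start=start,
        end=end,
        strand=strand,
        umi_observed=umi,
        calls=calls if calls is not None else {150: "A"},
        molecule_id=molecule_id,
    )


def duplex_family(prefix, umi_top, umi_bottom, n_top=2, n_bottom=2, **kwargs):
    """Reads of one molecule: top reads observe (u_top, u_bottom), bottom
    reads the swapped order, as the double-stranded barcode dictates."""
    reads = [
        make_read(f"{prefix}.t{i}", "top", (umi_top, umi_bottom), **kwargs)
        for i in range(n_top)
    ]
    reads += [
        make_read(f"{prefix}.b{i}", "bottom", (umi_bottom, umi_top), **kwargs)
        for i in range(n_bottom)
    ]
    return reads


@pytest.fixture
def fig_style_reads():
    """Eight reads, one fragment key, two duplex UMI families of four."""
    return duplex_family("m0", "AAAA", "CCCC", molecule_id=0) + duplex_family(
        "m1", "GGGG", "TTTT", molecule_id=1
    )
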