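import hypothesis
import pandas as pd
import pytest

from dasx import IntensityPanel, PANEL_COLUMNS, ProbesetAnnotation, ProbesetRecord

hypothesis.settings.register_profile(
    "default", derandomize=True, deadline=None, max_examples=50
)
hypothesis.settings.load_profile("default")


def make_record(pid="ps1", gene="g1", start=100, stop=200, seq_length=100,
                xhyb=False, chrom="chr1", strand="+"):
    return ProbesetRecord(
        probeset_id=pid, gene_id=gene, chrom=chrom, start=start, stop=stop,
        strand=strand, seq_length=seq_length, xhyb=xhyb,
    )


def make_panel(probeset_rows, gene_rows, dabg_rows=None):
    """Build an IntensityPanel from {id: [6 values in column order]}."""
    cols = list(PANEL_COLUMNS)
    ps = pd.DataFrame.from_dict(probeset_rows, orient="index", columns=cols)
    gn = pd.DataFrame.from_dict(gene_rows, orient="index", columns=cols)
    if dabg_rows is None:
        dabg_rows = {k: [0.001] * 6 for k in probeset_rows}
    db = pd.DataFrame.from_dict(dabg_rows, orient="index", columns=cols)
    return IntensityPanel(probeset_intensity=ps, gene_intensity=gn, dabg_p=db)


@pytest.fixture
def simple_annotation():
    return ProbesetAnnotation(
        [
            make_record("ps1", "g1", start=100, stop=200),
            make_record("ps2", "g1", start=300, stop=400),
            make_record("ps3", "g1", start=500, stop=600),
        ]
    )
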