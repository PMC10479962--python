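import numpy as np
import pandas as pd
import pytest

from omicsimage.types import GeneAnnotation, SampleProfile, Segment


@pytest.fixture
def toy_genes() -> GeneAnnotation:
    """Six genes on two chromosomes with easy round-number coordinates."""
    return GeneAnnotation(
        pd.DataFrame(
            {
                "gene_id": ["A", "B", "C", "D", "E", "F"],
                "chromosome": ["1", "1", "1", "2", "2", "2"],
                "start": [100, 400, 700, 100, 400, 700],
                "end": [200, 500, 800, 200, 500, 800],
            }
        )
    )


@pytest.fixture
def diploid_profile() -> SampleProfile:
    return SampleProfile("s1", ploidy=2.0, purity=0.8)


def make_segment(sample="s1", chrom="1", start=1, end=1000, cn=2.0) -> Segment:
    return Segment(sample, chrom, start, end, cn)
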