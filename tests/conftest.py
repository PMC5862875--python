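import numpy as np
import pandas as pd
import pytest

from mmcap.pipeline import demo_annotation
from mmcap.synthetic import CohortConfig, make_panel


@pytest.fixture(scope="session")
def annotation():
    return demo_annotation()


@pytest.fixture(scope="session")
def small_config():
    return CohortConfig(n_samples=2, probe_count=400, seed=7)


@pytest.fixture(scope="session")
def panel(small_config, annotation):
    return make_panel(small_config, annotation)


@pytest.fixture()
def rng():
    return np.random.default_rng(123)


def make_variants(rows):
    """Build a minimal MAF-like call table from (sample, gene, effect, vaf) rows."""
    out = []
    for i, (sample, gene, effect, vaf) in enumerate(rows):
        depth = 100
        alt = int(round(vaf * depth))
        out.append(
            dict(
                sample_id=sample, chrom="chr1", pos=1000 + i, ref="C", alt="T",
                gene=gene, effect=effect, ref_count=depth - alt, alt_count=alt,
                vaf=alt / depth, caller_flags="mutect", germline_flagged=False,
                in_igh=False, cosmic_annotated=False, deleterious_predicted=False,
            )
        )
    return pd.DataFrame(out)
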