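import pandas as pd
import pytest

from demeta import DEATable, DatasetMeta, parse_comparison_label


def build_table(
    rows,
    dataset_id="D1",
    species="human",
    technology="microarray",
    platform="synth",
    tissue="lung",
    comparison="IPF_vs_Ctrl",
    n_samples=10,
    biotype_scope="coding",
):
    """Build a DEATable from (feature, log2fc, p_nominal, p_adjusted) rows."""
    meta = DatasetMeta(
        dataset_id=dataset_id,
        species=species,
        technology=technology,
        platform=platform,
        tissue=tissue,
        comparison=parse_comparison_label(comparison),
        n_samples=n_samples,
        biotype_scope=biotype_scope,
    )
    df = pd.DataFrame(rows, columns=["feature", "log2fc", "p_nominal", "p_adjusted"])
    return DEATable(meta=meta, data=df.set_index("feature"))


@pytest.fixture
def make_table():
    return build_table
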