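import pytest

from lineagefate.data import CellRecord, TidyDataset
from lineagefate.design import design_matrix
from lineagefate.simulate import GenParams, simulate_dataset
from lineagefate.trees import build_trees


@pytest.fixture(scope="session")
def small_dataset():
    """A quick synthetic dataset: 8 founders/condition, default biology."""
    return simulate_dataset(GenParams(n_lineages=8), seed=11)


@pytest.fixture(scope="session")
def small_trees(small_dataset):
    return build_trees(small_dataset)


@pytest.fixture(scope="session")
def small_design(small_dataset):
    return design_matrix(small_dataset)


@pytest.fixture()
def tiny_csv(tmp_path):
    """Minimal canonical file: one root and two daughters."""
    text = (
        "lineage_id,cell_id,parent_id,cell_line,treatment,stage,t_birth,t_nebd,"
        "t_division,interphase_duration,mitotic_duration,micronuclei,bi_multi_nuclei,"
        "death,fading,tripolar,regression,fused_with,censored\n"
        "L1,a,,CTRL48,mCit,N+x,0,17,17.5,17,0.5,0,0,0,0,0,0,,0\n"
        "L1,aa,a,CTRL48,mCit,N+x,17.5,,,,,0,0,0,0,0,0,,1\n"
        "L1,ab,a,CTRL48,mCit,N+x,17.5,,,,,1,0,0,0,0,0,,1\n"
    )
    path = tmp_path / "tiny.csv"
    path.write_text(text)
    return path


def make_record(lineage_id="L1", cell_id="a", parent_id=None, cell_line="CTRL48",
                treatment="mCit", stage="N+x", t_birth=0.0, **kw) -> CellRecord:
    return CellRecord(lineage_id=lineage_id, cell_id=cell_id, parent_id=parent_id,
                      cell_line=cell_line, treatment=treatment, stage=stage,
                      t_birth=t_birth, **kw)


def make_dataset(records) -> TidyDataset:
    return TidyDataset(records=list(records))
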