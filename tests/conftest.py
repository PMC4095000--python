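import pytest

from cardionet.synthetic import paper_fixture
from cardionet.types import (
    Compound,
    CompoundClass,
    Dataset,
    LinkType,
    Location,
    PathwaySet,
    ProteinFamily,
    TargetAnnotation,
    TTDStatus,
    class_target_sets,
)


@pytest.fixture(scope="session")
def paper_ds():
    return paper_fixture()


@pytest.fixture(scope="session")
def paper_groups(paper_ds):
    return class_target_sets(paper_ds.compounds)


@pytest.fixture
def tiny_dataset():
    """A hand-built, fully consistent dataset small enough to reason about."""
    ann = {
        "T1": TargetAnnotation(
            "T1",
            "alpha",
            TTDStatus.SUCCESSFUL,
            frozenset({"d1", "d2"}),
            ("PF1",),
            ProteinFamily.ENZYME,
            frozenset({Location.CYTOPLASM}),
        ),
        "T2": TargetAnnotation(
            "T2",
            "beta",
            TTDStatus.RESEARCH,
            frozenset({"d1"}),
            ("PF1", "PF2"),
            ProteinFamily.RECEPTOR,
            frozenset({Location.PLASMA_MEMBRANE, Location.CYTOPLASM}),
            is_tf=True,
            tf_gene_count=3,
        ),
        "T3": TargetAnnotation(
            "T3",
            "gamma",
            TTDStatus.ABSENT,
            frozenset(),
            (),
            ProteinFamily.ENZYME,
            frozenset({Location.NUCLEUS}),
        ),
    }
    compounds = [
        Compound(
            "H1",
            "herb one",
            CompoundClass.HERBAL_INGREDIENT,
            [("T1", LinkType.DIRECT), ("T2", LinkType.DIRECT), ("T3", LinkType.INDIRECT)],
        ),
        Compound("W1", "drug one", CompoundClass.WESTERN_DRUG, [("T2", LinkType.DIRECT)]),
    ]
    pathways = [
        PathwaySet("P1", "basic tiny pathway", members=frozenset({"T1", "T2"})),
    ]
    return Dataset(compounds=compounds, annotations=ann, pathways=pathways, universe_size=100)
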