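import pytest

from ttdrank import (
    CorpusConfig,
    Direction,
    ModelTier,
    RelationshipClass,
    TTDRecord,
    TruthEntry,
    TruthTable,
    generate_corpus,
    truth_lexicon,
)


def make_record(
    rec_id=1,
    molecule="BRAF",
    state="mut V600E",
    drug="sorafenib",
    hypothesis=1,
    model=ModelTier.ANIMAL_IN_VITRO,
    relationship_class=RelationshipClass.EFFICACY,
    cases=None,
    **kwargs,
):
    """Build a valid record with sensible defaults for tests."""
    return TTDRecord(
        id=rec_id,
        source=kwargs.pop("source", "melanoma specimen"),
        molecule=molecule,
        state=state,
        relationship_class=relationship_class,
        direction=Direction(hypothesis),
        drug=drug,
        model=model,
        hypothesis=hypothesis,
        reference=kwargs.pop("reference", f"Ref {rec_id}"),
        notes=kwargs.pop("notes", ""),
        cases=cases,
        modifier=kwargs.pop(
            "modifier",
            "MEK inhibitor" if relationship_class is RelationshipClass.SYNERGISM else None,
        ),
        **kwargs,
    )


@pytest.fixture
def small_table():
    """Five handmade records: two groups plus uveal-melanoma tagged rows."""
    return [
        make_record(1, hypothesis=1, model=ModelTier.HUMAN_IN_VITRO),
        make_record(2, hypothesis=1, model=ModelTier.ANIMAL_IN_VITRO),
        make_record(3, hypothesis=-1, model=ModelTier.ANIMAL_IN_VITRO),
        make_record(
            4,
            molecule="KIT",
            state="mut L576P",
            drug="imatinib",
            hypothesis=1,
            model=ModelTier.CLINICAL_STUDY,
            cases=40,
            notes="Uveal melanoma; small series",
        ),
        make_record(
            5,
            molecule="KIT",
            state="mut L576P",
            drug="imatinib",
            hypothesis=0,
            model=ModelTier.HUMAN_IN_VITRO,
            notes="uveal melanoma cell line",
        ),
    ]


@pytest.fixture
def truth_table():
    return TruthTable(
        [
            TruthEntry("MOL001", "mut M1", "DRUG_A", Direction.POSITIVE, 0.9),
            TruthEntry("MOL002", "mut M2", "DRUG_A", Direction.NEGATIVE, 0.9),
            TruthEntry("MOL001", "mut M1", "DRUG_B", Direction.NEGATIVE, 0.9),
            TruthEntry("MOL003", "mut M3", "DRUG_B", Direction.NULL, 0.9),
        ]
    )


@pytest.fixture
def corpus(truth_table):
    return generate_corpus(CorpusConfig(truth=truth_table, studies_per_group=20, seed=42))


@pytest.fixture
def lexicon(truth_table):
    return truth_lexicon(truth_table)
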