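import pytest

from flourmap import (
    IncidenceMap,
    ProteinRecord,
    SequenceDatabase,
    parse_catalogue_tables,
)


@pytest.fixture(scope="session")
def spot125_incidence() -> IncidenceMap:
    """The published worked example: two homologous LMW-GS in one spot,
    12 peptides unique to A, 5 unique to B, 4 shared (21 peptides)."""
    peptides = {}
    for i in range(12):
        peptides[f"uniqA_{i:02d}"] = frozenset({"A"})
    for i in range(5):
        peptides[f"uniqB_{i:02d}"] = frozenset({"B"})
    for i in range(4):
        peptides[f"shared_{i:02d}"] = frozenset({"A", "B"})
    return IncidenceMap("125", peptides, {p: 1 for p in peptides})


@pytest.fixture(scope="session")
def toy_db() -> SequenceDatabase:
    """Small annotated database with one peptide unique to the first
    alpha-gliadin and prolamin-style repetitive sequences."""
    return SequenceDatabase([
        ProteinRecord(
            id="agli1",
            sequence="VRVPVPQLQLQPFPQPQLSYSQPQPFRPQQPYPQPQPQY",
            family="alpha-gliadin",
            genome="A",
            cultivar_specific=True,
        ),
        ProteinRecord(
            id="agli2",
            sequence="VRVPVPQLQPQHPSQQQPQEQVPLSQPQPFRPQQPYPQPQPQY",
            family="alpha-gliadin",
            genome="B",
        ),
        ProteinRecord(
            id="lmw1",
            sequence="QMENSHIPGLERPSQQQPLPPQQTLSHHHQQQKVDQESRSHH",
            family="LMW-GS",
            genome="B",
            cultivar_specific=True,
            signal_len=0,
        ),
    ])


@pytest.fixture(scope="session")
def catalogue_tables():
    """Packaged spot-catalogue fixtures: (quants, assignment)."""
    return parse_catalogue_tables()
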