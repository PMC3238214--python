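"""Map observed peptides onto the sequence database.

Peptide-spectrum matches arrive as already-validated peptide sequences
(engine scoring is upstream of this package); mapping is exact
substring search against target records, optionally treating I and L as
equivalent position-by-position (tandem MS cannot distinguish them).
The per-spot bipartite peptide-protein structure (the incidence map)
with each peptide classed unique / shared / orphan is what protein
inference consumes.  Also here: detection of processed N-terminal forms
(pyroglutamate loss, SHIP- and KEL-type proteolytic trimming) and
scanning for user-supplied celiac epitope motifs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import pandas as pd

from .sequence_db import SequenceDatabase, MatureProtein

_IL_FOLD = str.maketrans("L", "I")


@dataclass(frozen=True)
class PeptideObservation:
    """One identified peptide in one spot."""

    spot_id: str
    protease: str
    sequence: str
    spectra_count: int = 1
    ppm_error: float = 0.0
    probability: float = 1.0

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("empty peptide sequence")
        if self.spectra_count < 1:
            raise ValueError("spectra_count must be >= 1")
        if not 0.0 <= self.probability <= 1.0:
            raise ValueError(f"probability outside [0,1]: {self.probability}")


@dataclass
class IncidenceMap:
    """Per-spot bipartite structure: peptide -> matching protein ids."""

    spot_id: str
    peptides: dict[str, frozenset]  # peptide sequence -> protein id set
    spectra: dict[str, int]  # peptide sequence -> summed spectra count

    def uniqueness(self, peptide: str) -> str:
        ids = self.peptides[peptide]
        if not ids:
            return "orphan"
        return "unique" if len(ids) == 1 else "shared"

    def unique_peptides(self) -> set[str]:
        return {p for p in self.peptides if self.uniqueness(p) == "unique"}

    def shared_peptides(self) -> set[str]:
        return {p for p in self.peptides if self.uniqueness(p) == "shared"}

    def orphans(self) -> set[str]:
        return {p for p in self.peptides if self.uniqueness(p) == "orphan"}

    def proteins(self) -> set[str]:
        out: set[str] = set()
        for ids in self.peptides.values():
            out |= ids
        return out

    def peptides_of(self, protein_id: str) -> set[str]:
        return {p for p, ids in self.peptides.items() if protein_id in ids}


def map_peptide(
    sequence: str, db: SequenceDatabase, il_equivalent: bool = False
) -> frozenset:
    """Ids of all target records containing the peptide as a substring.

    With ``il_equivalent`` an I in the peptide matches an L in the
    protein and vice versa (positionwise substitution only).  Decoys are
    never reported.
    """
    needle = sequence.translate(_IL_FOLD) if il_equivalent else sequence
    hits = []
    for rec in db:
        if rec.is_decoy:
            continue
        hay = rec.sequence.translate(_IL_FOLD) if il_equivalent else rec.sequence
        if needle in hay:
            hits.append(rec.id)
    return frozenset(hits)


def build_incidence(
    observations: Sequence[PeptideObservation],
    db: SequenceDatabase,
    il_equivalent: bool = False,
) -> IncidenceMap:
    """Deduplicate one spot's observations into an incidence map.

    Repeated observations of a peptide collapse to one entry with
    summed spectra counts; orphan peptides (matching no target) are
    retained so that they can be reported, not silently dropped.
    """
    if not observations:
        raise ValueError("no observations")
    spot_ids = {o.spot_id for o in observations}
    if len(spot_ids) != 1:
        raise ValueError(f"observations span several spots: {sorted(spot_ids)}")
    peptides: dict[str, frozenset] = {}
    spectra: dict[str, int] = {}
    for obs in observations:
        spectra[obs.sequence] = spectra.get(obs.sequence, 0) + obs.spectra_count
        if obs.sequence not in peptides:
            peptides[obs.sequence] = map_peptide(obs.sequence, db, il_equivalent)
    return IncidenceMap(spot_id=spot_ids.pop(), peptides=peptides, spectra=spectra)


# Known N-terminal processing offsets of wheat storage proteins:
# 0 = intact mature N-terminus; 1 = loss of the first Gln
# (pyroglutamate formation); 4 = cleavage after the Asn of QMEN,
# yielding SHIP-type termini; 8 = removal of the first eight residues
# of ARQL-type omega-gliadins, yielding KEL-type termini.
DEFAULT_PROCESSING_OFFSETS: dict[int, str] = {
    0: "mature",
    1: "des-Q1",
    4: "QMEN-trimmed",
    8: "omega-KEL",
}


def detect_n_termini(
    mature: Union[MatureProtein, str],
    observations: Sequence[PeptideObservation],
    offsets: Optional[Mapping[int, str]] = None,
) -> list[tuple[str, int, str]]:
    """Observed N-terminal forms of a mature protein.

    Each observation whose sequence is a literal prefix of the mature
    sequence at one of the declared processing offsets is reported as
    ``(form_label, offset, peptide)``.
    """
    seq = mature if isinstance(mature, str) else mature.mature_sequence
    table = dict(DEFAULT_PROCESSING_OFFSETS if offsets is None else offsets)
    forms: list[tuple[str, int, str]] = []
    for obs in observations:
        for off in sorted(table):
            if seq[off:].startswith(obs.sequence):
                forms.append((table[off], off, obs.sequence))
                break
    return forms


@dataclass
class EpitopeLibrary:
    """Named exact-sequence motifs (e.g. celiac T-cell epitopes)."""

    motifs: dict[str, str]
    sources: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, motif in self.motifs.items():
            if not motif:
                raise ValueError(f"motif {name!r} is empty")


def load_epitopes(path: str | Path) -> EpitopeLibrary:
    """Read an epitope library TSV with columns name, sequence, source."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    motifs = dict(zip(df["name"], df["sequence"]))
    sources = dict(zip(df["name"], df.get("source", pd.Series(dtype=str)).fillna("")))
    return EpitopeLibrary(motifs=motifs, sources=sources)


_QE_FOLD = str.maketrans("E", "Q")


def scan_epitopes(
    sequence: str,
    library: EpitopeLibrary,
    deamidation_equivalent: bool = False,
) -> list[tuple[str, int]]:
    """All exact motif matches in a sequence, overlapping allowed.

    Returns ``(motif_name, 1-based position)`` pairs.  With
    ``deamidation_equivalent`` Q and E match each other, approximating
    recognition of transglutaminase-deamidated peptides.
    """
    hay = sequence.translate(_QE_FOLD) if deamidation_equivalent else sequence
    matches: list[tuple[str, int]] = []
    for name in sorted(library.motifs):
        motif = library.motifs[name]
        needle = motif.translate(_QE_FOLD) if deamidation_equivalent else motif
        start = 0
        while True:
            idx = hay.find(needle, start)
            if idx < 0:
                break
            matches.append((name, idx + 1))
            start = idx + 1
    return matches


# --- observation table I/O --------------------------------------------------

OBSERVATION_COLUMNS = [
    "spot_id", "protease", "peptide", "spectra", "ppm", "probability",
]


def read_observations(path: str | Path) -> list[PeptideObservation]:
    """Read a peptide-evidence TSV (one row per observed peptide)."""
    df = pd.read_csv(path, sep="\t", dtype={"spot_id": str})
    return [
        PeptideObservation(
            spot_id=str(row.spot_id),
            protease=str(row.protease),
            sequence=str(row.peptide),
            spectra_count=int(row.spectra),
            ppm_error=float(row.ppm),
            probability=float(row.probability),
        )
        for row in df.itertuples()
    ]


def write_observations(
    observations: Iterable[PeptideObservation], path: str | Path
) -> None:
    df = pd.DataFrame(
        [
            (o.spot_id, o.protease, o.sequence, o.spectra_count, o.ppm_error,
             o.probability)
            for o in observations
        ],
        columns=OBSERVATION_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)
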