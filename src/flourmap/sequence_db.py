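"""Protein sequence database: FASTA I/O, annotation, decoys, subsets.

Records carry the annotations a flour-proteome analysis needs (storage
protein family, locus, genome of origin in hexaploid wheat, whether the
sequence is cultivar-specific, signal-peptide length) in structured
FASTA header tokens of the form ``>id key=value ...`` so a database is
a single self-describing file.  Decoy sequences for target-decoy FDR
share the database with targets but are flagged and carry a reserved
id prefix.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Optional

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import chem

FAMILIES = frozenset({
    "HMW-GS", "LMW-GS", "gamma-gliadin", "omega-gliadin", "alpha-gliadin",
    "farinin", "purinin", "triticin", "globulin", "GSP/puroindoline",
    "amylase/protease-inhibitor", "serpin", "enzyme", "other", "unknown",
})

GENOMES = frozenset({"A", "B", "D", "unknown"})

DECOY_PREFIX = "DECOY_"

_ALPHABET = chem.AMINO_ACIDS | {"X"}


@dataclass(frozen=True)
class ProteinRecord:
    """One database sequence with its annotations."""

    id: str
    sequence: str
    description: str = ""
    family: str = "unknown"
    locus: Optional[str] = None
    genome: Optional[str] = None
    cultivar_specific: bool = False
    signal_len: Optional[int] = None
    partial: bool = False
    is_decoy: bool = False
    aliases: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record id must be non-empty")
        if not self.sequence:
            raise ValueError(f"record {self.id!r}: empty sequence")
        for i, aa in enumerate(self.sequence):
            if aa not in _ALPHABET:
                raise ValueError(
                    f"record {self.id!r}: invalid residue {aa!r} at position {i + 1}"
                )
        if self.family not in FAMILIES:
            raise ValueError(f"record {self.id!r}: unknown family {self.family!r}")
        if self.genome is not None and self.genome not in GENOMES:
            raise ValueError(f"record {self.id!r}: unknown genome {self.genome!r}")
        if self.signal_len is not None:
            if self.signal_len < 0:
                raise ValueError(f"record {self.id!r}: negative signal_len")
            if self.signal_len >= len(self.sequence):
                raise ValueError(
                    f"record {self.id!r}: signal_len {self.signal_len} >= "
                    f"sequence length {len(self.sequence)}"
                )
        if not self.is_decoy and self.id.startswith(DECOY_PREFIX):
            raise ValueError(
                f"target record id {self.id!r} uses the reserved decoy prefix"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class MatureProtein:
    """Mature (signal-trimmed) form of a precursor, with MW and pI."""

    parent_id: str
    mature_sequence: str
    mw_da: float
    pi: float


class SequenceDatabase:
    """Keyed collection of :class:`ProteinRecord`, targets plus decoys."""

    def __init__(self, records: Iterable[ProteinRecord] = ()) -> None:
        self._records: dict[str, ProteinRecord] = {}
        for rec in records:
            self.add(rec)

    def add(self, record: ProteinRecord) -> None:
        if record.id in self._records:
            raise ValueError(f"duplicate record id {record.id!r}")
        self._records[record.id] = record

    def __getitem__(self, record_id: str) -> ProteinRecord:
        return self._records[record_id]

    def __contains__(self, record_id: str) -> bool:
        return record_id in self._records

    def __iter__(self) -> Iterator[ProteinRecord]:
        return iter(self._records.values())

    def __len__(self) -> int:
        return len(self._records)

    @property
    def records(self) -> Mapping[str, ProteinRecord]:
        return dict(self._records)

    def targets(self) -> list[ProteinRecord]:
        return [r for r in self if not r.is_decoy]

    def decoys(self) -> list[ProteinRecord]:
        return [r for r in self if r.is_decoy]

    @property
    def n_targets(self) -> int:
        return len(self.targets())

    @property
    def n_decoys(self) -> int:
        return len(self.decoys())


# --- FASTA header dialect ---------------------------------------------------

_BOOL_KEYS = {"cultivar": "cultivar_specific", "partial": "partial", "decoy": "is_decoy"}


def _record_from_header(name: str, description: str, sequence: str) -> ProteinRecord:
    kwargs: dict = {"id": name, "sequence": sequence}
    free_text: list[str] = []
    tokens = description.split()[1:]  # first token is the id itself
    for tok in tokens:
        if "=" not in tok:
            free_text.append(tok)
            continue
        key, _, value = tok.partition("=")
        if key == "family":
            kwargs["family"] = value
        elif key == "locus":
            kwargs["locus"] = value
        elif key == "genome":
            kwargs["genome"] = value
        elif key == "signal_len":
            kwargs["signal_len"] = int(value)
        elif key == "aliases":
            kwargs["aliases"] = tuple(value.split(","))
        elif key in _BOOL_KEYS:
            kwargs[_BOOL_KEYS[key]] = value in {"1", "true", "True"}
        else:
            free_text.append(tok)
    kwargs["description"] = " ".join(free_text)
    if name.startswith(DECOY_PREFIX):
        kwargs["is_decoy"] = True
    return ProteinRecord(**kwargs)


def _header_for(rec: ProteinRecord) -> str:
    parts: list[str] = []
    if rec.family != "unknown":
        parts.append(f"family={rec.family}")
    if rec.locus:
        parts.append(f"locus={rec.locus}")
    if rec.genome:
        parts.append(f"genome={rec.genome}")
    if rec.cultivar_specific:
        parts.append("cultivar=1")
    if rec.signal_len is not None:
        parts.append(f"signal_len={rec.signal_len}")
    if rec.partial:
        parts.append("partial=1")
    if rec.is_decoy:
        parts.append("decoy=1")
    if rec.aliases:
        parts.append("aliases=" + ",".join(rec.aliases))
    if rec.description:
        parts.append(rec.description)
    return " ".join(parts)


def read_fasta(path: str | Path) -> SequenceDatabase:
    """Read a FASTA file with ``key=value`` header annotation tokens."""
    db = SequenceDatabase()
    for seqrec in SeqIO.parse(str(path), "fasta"):
        seq = str(seqrec.seq).upper()
        if not seq:
            raise ValueError(f"record {seqrec.id!r}: empty sequence entry")
        db.add(_record_from_header(seqrec.id, seqrec.description, seq))
    return db


def write_fasta(db: SequenceDatabase, path: str | Path) -> None:
    """Write the database back out, headers round-tripping all annotations."""
    records = [
        SeqRecord(Seq(rec.sequence), id=rec.id, description=_header_for(rec))
        for rec in db
    ]
    with open(path, "w") as handle:
        SeqIO.write(records, handle, "fasta")


# --- transformations --------------------------------------------------------


def concatenate(
    databases: list[SequenceDatabase], dedupe: bool = False
) -> SequenceDatabase:
    """Union of several databases.

    With ``dedupe`` records holding byte-identical sequences are merged,
    all ids kept as aliases on the first-seen record (I and L remain
    distinct: deduplication is exact string equality).
    """
    if not databases:
        raise ValueError("need at least one database")
    out = SequenceDatabase()
    by_seq: dict[str, str] = {}
    for db in databases:
        for rec in db:
            if rec.id in out:
                if out[rec.id].sequence != rec.sequence:
                    raise ValueError(
                        f"id collision with different sequences: {rec.id!r}"
                    )
                continue
            if dedupe and rec.sequence in by_seq:
                keeper_id = by_seq[rec.sequence]
                keeper = out[keeper_id]
                merged = replace(
                    keeper, aliases=tuple(keeper.aliases) + (rec.id,) + rec.aliases
                )
                out._records[keeper_id] = merged
                continue
            out.add(rec)
            if dedupe:
                by_seq.setdefault(rec.sequence, rec.id)
    return out


def trim_signal(
    record: ProteinRecord,
    signal_len: Optional[int] = None,
    mass_mode: str = "average",
    pka_table: str = "bjellqvist",
) -> MatureProtein:
    """Derive the mature protein by removing the N-terminal signal peptide.

    The cleavage site is an annotation input (``signal_len`` on the record
    or the override argument), not a prediction.  MW and pI are computed
    from the mature sequence.
    """
    n = signal_len if signal_len is not None else record.signal_len
    if n is None:
        raise ValueError(
            f"record {record.id!r}: no signal_len annotated and none supplied"
        )
    if n >= len(record.sequence):
        raise ValueError(
            f"record {record.id!r}: signal_len {n} >= length {len(record.sequence)}"
        )
    mature = record.sequence[n:]
    return MatureProtein(
        parent_id=record.id,
        mature_sequence=mature,
        mw_da=chem.molecular_weight(mature, mass_mode),
        pi=chem.isoelectric_point(mature, pka_table),
    )


molecular_weight = chem.molecular_weight
isoelectric_point = chem.isoelectric_point


def _make_decoy(rec: ProteinRecord, method: str, rng: random.Random) -> ProteinRecord:
    if method == "reverse":
        seq = rec.sequence[::-1]
    elif method == "shuffle":
        chars = list(rec.sequence)
        rng.shuffle(chars)
        seq = "".join(chars)
    else:
        raise ValueError(f"unknown decoy method {method!r}")
    return ProteinRecord(
        id=DECOY_PREFIX + rec.id,
        sequence=seq,
        description=f"decoy of {rec.id}",
        is_decoy=True,
    )


def generate_decoys(
    db: SequenceDatabase, method: str = "reverse", seed: Optional[int] = None
) -> SequenceDatabase:
    """Append one decoy per target (reversed, or seeded shuffle)."""
    if db.n_decoys:
        raise ValueError("database already contains decoys")
    rng = random.Random(seed)
    out = SequenceDatabase(db)
    for rec in db.targets():
        out.add(_make_decoy(rec, method, rng))
    return out


def build_subset(
    db: SequenceDatabase,
    protein_probabilities: Mapping[str, float],
    threshold: float = 0.20,
    extras: Optional[SequenceDatabase] = None,
    seed: Optional[int] = None,
    decoy_method: str = "reverse",
) -> SequenceDatabase:
    """Second-pass subset database.

    Retains every scored target at or above the probability threshold,
    adds the extra sequences (deduplicated by id), then appends exactly
    one decoy per retained sequence.
    """
    for pid, p in protein_probabilities.items():
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"probability for {pid!r} outside [0,1]: {p}")
    retained = [
        db[pid]
        for pid in sorted(protein_probabilities)
        if protein_probabilities[pid] >= threshold and not db[pid].is_decoy
    ]
    out = SequenceDatabase(retained)
    if extras is not None:
        for rec in extras:
            if rec.id not in out:
                out.add(rec)
    rng = random.Random(seed)
    for rec in list(out):
        out.add(_make_decoy(rec, decoy_method, rng))
    return out
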