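"""Spot-volume quantification and aggregation.

2-DE quantification in this pipeline is relative: each spot's volume is
expressed as a percent of the summed spot volume of its gel
(``raw / total x 100``), then averaged over biological replicate gels.
Identified spots carry an assignment (predominant protein, storage
protein family, locus group, genome of origin) and their normalized
volumes roll up additively to protein, family, locus, genome or
celiac-epitope-class totals.  Mixed spots -- no strict-majority
predominant protein -- form their own family-level category and are
never split among their constituent proteins.

The packaged fixture tables transcribe a published flour-proteome
spot catalogue (231 identified spots accounting for 93.09% of total
normalized volume) and exercise the same arithmetic.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

TABLE_FILES = [
    "table3_hmw_gs.tsv",
    "table4_lmw_gs.tsv",
    "table5_gamma_gliadins.tsv",
    "table6_omega_gliadins.tsv",
    "table7_alpha_gliadins.tsv",
    "table8_minor_storage.tsv",
    "table9_inhibitors.tsv",
    "table10_enzymes.tsv",
]


@dataclass(frozen=True)
class GelSpotTable:
    """Raw spot volumes of one gel."""

    gel_id: str
    volumes: Mapping[str, float]

    def __post_init__(self) -> None:
        for spot, v in self.volumes.items():
            if v < 0:
                raise ValueError(f"gel {self.gel_id}: negative volume for {spot}")
        if not any(v > 0 for v in self.volumes.values()):
            raise ValueError(f"gel {self.gel_id}: no positive volume")


@dataclass
class SpotQuant:
    """Normalized volume of one spot: mean +/- SD over replicates."""

    spot_id: str
    mean_volume: float
    sd_volume: float
    n_replicates: int
    censored: bool = False  # parsed from a "<0.01"-style entry


@dataclass(frozen=True)
class SpotAssignment:
    """Identification attached to one spot."""

    spot_id: str
    protein: str
    family: str
    group: Optional[str] = None  # locus-level label, e.g. "Glu-B1" or "QMET-type"
    genome: Optional[str] = None
    mixed: bool = False
    n_proteins: Optional[int] = None
    celiac: Optional[str] = None  # epitope codes column, alpha-gliadins only


class AssignmentMap:
    """spot id -> assignment; every spot is assigned, mixed, or absent."""

    def __init__(self, assignments: Iterable[SpotAssignment] = ()) -> None:
        self._by_spot: dict[str, SpotAssignment] = {}
        for a in assignments:
            self.add(a)

    def add(self, a: SpotAssignment) -> None:
        if a.spot_id in self._by_spot:
            raise ValueError(f"spot {a.spot_id!r} assigned twice")
        self._by_spot[a.spot_id] = a

    def __getitem__(self, spot_id: str) -> SpotAssignment:
        return self._by_spot[spot_id]

    def __contains__(self, spot_id: str) -> bool:
        return spot_id in self._by_spot

    def __iter__(self):
        return iter(self._by_spot.values())

    def __len__(self) -> int:
        return len(self._by_spot)


@dataclass
class AggregateReport:
    """Volume roll-up at one grouping level."""

    level: str
    groups: dict[str, dict]  # group -> {"total": float, "n_spots": int}

    @property
    def grand_total(self) -> float:
        return sum(g["total"] for g in self.groups.values())


def normalize(gel: GelSpotTable) -> dict[str, float]:
    """Per-spot percent of the gel's total volume; sums to 100."""
    total = sum(gel.volumes.values())
    if total <= 0:
        raise ValueError(f"gel {gel.gel_id}: zero total volume")
    return {spot: v / total * 100.0 for spot, v in gel.volumes.items()}


def replicate_stats(
    normalized_gels: Sequence[Mapping[str, float]]
) -> dict[str, SpotQuant]:
    """Mean and sample SD of normalized volumes over replicate gels.

    A spot missing from one gel contributes as missing (its n is
    decremented), not as zero.
    """
    if len(normalized_gels) < 2:
        raise ValueError("need at least two replicate gels")
    spots: set[str] = set()
    for gel in normalized_gels:
        spots |= set(gel)
    shared = set.intersection(*(set(g) for g in normalized_gels))
    if not shared:
        raise ValueError("replicate gels share no spot ids")
    out: dict[str, SpotQuant] = {}
    for spot in sorted(spots):
        values = [g[spot] for g in normalized_gels if spot in g]
        n = len(values)
        mean = sum(values) / n
        sd = math.sqrt(sum((v - mean) ** 2 for v in values) / (n - 1)) if n > 1 else 0.0
        out[spot] = SpotQuant(spot, mean, sd, n)
    return out


def _parse_volume(text: str, row_context: str) -> tuple[Optional[float], bool]:
    """Returns (value, censored); None for a missing entry."""
    text = text.strip()
    if text in {"", "-", "nd", "inc", "NA"}:
        return None, False
    if text.startswith("<"):
        return 0.0, True
    try:
        return float(text), False
    except ValueError as exc:
        raise ValueError(f"malformed numeric {text!r} in {row_context}") from exc


def _table_frames(paths: Optional[Sequence[str | Path]]) -> list[pd.DataFrame]:
    frames = []
    if paths is not None:
        for p in paths:
            frames.append(pd.read_csv(p, sep="\t", comment="#", dtype=str).fillna(""))
        return frames
    base = resources.files("flourmap.data") / "tables"
    for name in TABLE_FILES:
        with (base / name).open() as fh:
            frames.append(pd.read_csv(fh, sep="\t", comment="#", dtype=str).fillna(""))
    return frames


def parse_catalogue_tables(
    paths: Optional[Sequence[str | Path]] = None,
) -> tuple[dict[str, SpotQuant], AssignmentMap]:
    """Load the packaged spot-catalogue fixture tables.

    Censored volumes ("<0.01") parse as 0.0 with the censored flag set;
    "inc"/"nd"/"-" entries parse as missing, never as zero.  When a
    spot appears in more than one table (a known catalogue quirk), the
    volume-bearing row is kept as its assignment.
    """
    quants: dict[str, SpotQuant] = {}
    assignment = AssignmentMap()
    for df in _table_frames(paths):
        for row in df.itertuples():
            ctx = f"{getattr(row, 'table', '?')} spot {row.spot_id}"
            volume, censored = _parse_volume(str(row.volume), ctx)
            sd, _ = _parse_volume(str(row.sd), ctx)
            spot_id = str(row.spot_id)
            if spot_id in assignment and volume is None:
                continue  # secondary volume-less listing of a duplicate spot
            if spot_id in assignment:
                raise ValueError(f"spot {spot_id!r} listed twice with volumes")
            n_proteins = int(row.n_proteins) if str(row.n_proteins) else None
            assignment.add(
                SpotAssignment(
                    spot_id=spot_id,
                    protein=str(row.protein),
                    family=str(row.family),
                    group=str(row.group) or None,
                    genome=str(row.genome) or None,
                    mixed=str(row.family) == "mixed",
                    n_proteins=n_proteins,
                    celiac=str(getattr(row, "celiac", "")) or None,
                )
            )
            if volume is not None:
                quants[spot_id] = SpotQuant(
                    spot_id=spot_id,
                    mean_volume=volume,
                    sd_volume=sd if sd is not None else 0.0,
                    n_replicates=3,
                    censored=censored,
                )
    return quants, assignment


def _celiac_class(codes: Optional[str]) -> str:
    if codes is None or codes in {"", "inc", "nd"}:
        return "unscored"
    if codes == "-":
        return "epitope-free"
    if "5" in codes:
        return "33-mer"
    if "6" in codes:
        return "p31-43"
    return "other-epitopes"


def aggregate(
    quants: Mapping[str, SpotQuant],
    assignment: AssignmentMap,
    level: str = "family",
    within_family: Optional[str] = None,
) -> AggregateReport:
    """Sum spot volumes into groups at the requested level.

    Levels: ``protein`` (predominant protein label), ``family``
    (mixed spots form their own group), ``locus`` (the table's
    locus-level group label), ``genome``, ``celiac_class``.
    ``within_family`` restricts the roll-up to one family's spots
    (e.g. per-protein shares of the HMW-GS total).  Volume is conserved:
    the group totals sum to the summed member-spot volumes exactly.
    """
    levels = {"protein", "family", "locus", "genome", "celiac_class"}
    if level not in levels:
        raise ValueError(f"unknown level {level!r}; have {sorted(levels)}")
    groups: dict[str, dict] = {}
    for spot_id in quants:
        if spot_id not in assignment:
            continue
        a = assignment[spot_id]
        if within_family is not None and a.family != within_family:
            continue
        if level == "protein":
            key = a.protein
        elif level == "family":
            key = "mixed" if a.mixed else a.family
        elif level == "locus":
            key = a.group or "unknown"
        elif level == "genome":
            key = a.genome or "unknown"
        else:
            key = _celiac_class(a.celiac)
        entry = groups.setdefault(key, {"total": 0.0, "n_spots": 0})
        entry["total"] += quants[spot_id].mean_volume
        entry["n_spots"] += 1
    return AggregateReport(level=level, groups=groups)


def identified_summary(
    quants: Mapping[str, SpotQuant], assignment: AssignmentMap
) -> dict:
    """Grand totals: identified spot count and volume (of 100)."""
    identified = [s for s in quants if s in assignment]
    total = sum(quants[s].mean_volume for s in identified)
    return {
        "n_identified": len(assignment),
        "identified_volume": total,
        "unidentified_volume": 100.0 - total,
    }


def round1(x: float) -> float:
    """Round half away from zero to one decimal (presentation only)."""
    return math.copysign(math.floor(abs(x) * 10 + 0.5) / 10, x)


def share_percent(part: float, whole: float) -> float:
    """Percent-of-parent value, rounded to one printed decimal."""
    if whole == 0:
        raise ValueError("zero denominator")
    return round1(part / whole * 100.0)


def charge_trains(
    assignment: AssignmentMap,
    quants: Optional[Mapping[str, SpotQuant]] = None,
    family: Optional[str] = None,
) -> dict:
    """Group spots by predominant protein into charge trains.

    A protein resolved in several spots of stepped pI forms one train.
    Returns per-train spot lists and volume totals plus the mean number
    of spots per protein.
    """
    trains: dict[str, dict] = {}
    for a in assignment:
        if a.mixed:
            continue
        if family is not None and a.family != family:
            continue
        t = trains.setdefault(a.protein, {"spots": [], "total_volume": 0.0})
        t["spots"].append(a.spot_id)
        if quants is not None and a.spot_id in quants:
            t["total_volume"] += quants[a.spot_id].mean_volume
    n_proteins = len(trains)
    n_spots = sum(len(t["spots"]) for t in trains.values())
    return {
        "trains": trains,
        "n_proteins": n_proteins,
        "n_spots": n_spots,
        "mean_spots_per_protein": n_spots / n_proteins if n_proteins else 0.0,
    }


def report(
    aggregates: Sequence[AggregateReport],
    summary: Optional[dict] = None,
    out_dir: Optional[str | Path] = None,
) -> dict:
    """Emit a deterministic summary (and TSV/JSON files if requested)."""
    if not aggregates:
        raise ValueError("need at least one aggregate")
    doc: dict = {"levels": {}}
    rows = []
    for agg in aggregates:
        ordered = {
            k: {"total": agg.groups[k]["total"], "n_spots": agg.groups[k]["n_spots"]}
            for k in sorted(agg.groups)
        }
        doc["levels"][agg.level] = ordered
        for k, v in ordered.items():
            rows.append((agg.level, k, v["n_spots"], v["total"]))
    if summary:
        doc["summary"] = summary
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(
            rows, columns=["level", "group", "n_spots", "total_volume"]
        ).to_csv(out / "aggregates.tsv", sep="\t", index=False)
        with open(out / "aggregates.json", "w") as fh:
            json.dump(doc, fh, indent=2, sort_keys=True)
    return doc
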