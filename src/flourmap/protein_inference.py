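"""Per-spot protein inference.

Two assignment strategies are provided side by side because they can
disagree on homolog-rich spots:

* ``greedy_assign`` reproduces the Scaffold-style behaviour: repeatedly
  take the protein explaining the most still-unassigned peptides and
  credit it with *all* of them, shared peptides included.  This
  overstates the dominant homoeolog and understates the minor ones.

* ``parsimony_assign`` selects the preference-minimal protein set whose
  union covers every mappable peptide (exact branch-and-bound search for
  small candidate sets), then credits shared peptides only to accepted
  proteins that also own at least one unique peptide, recording the
  ambiguity whenever several qualify.  Preference favours (i) fewer
  proteins, (ii) more cultivar-specific sequences, (iii) more unique
  peptides covered, (iv) lexicographic ids -- i.e. a cultivar-matched
  sequence that explains everything beats a patchwork of public
  homologs.

Upstream of both sits PSM filtering with the acceptance thresholds used
for the flour dataset (>=2 distinct peptides per protein, |mass error|
<= 100 ppm inclusive, peptide probability > 0.90 strict), and
downstream a simple target-decoy FDR estimate (decoys accepted /
targets accepted).
"""

from __future__ import annotations

import itertools
import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .peptide_mapping import (
    IncidenceMap,
    PeptideObservation,
    build_incidence,
)
from .sequence_db import SequenceDatabase

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PsmFilterConfig:
    """Acceptance thresholds for peptide-spectrum matches."""

    min_peptides: int = 2
    max_ppm: float = 100.0
    min_probability: float = 0.90

    def __post_init__(self) -> None:
        if self.min_peptides < 1:
            raise ValueError("min_peptides must be >= 1")
        if self.max_ppm <= 0:
            raise ValueError("max_ppm must be positive")
        if not 0.0 <= self.min_probability <= 1.0:
            raise ValueError("min_probability outside [0,1]")


@dataclass
class InferenceResult:
    """Outcome of one spot's protein assignment."""

    spot_id: str
    mode: str  # "greedy" | "parsimony"
    accepted: list[str]
    predominant: Optional[str]
    assignment: dict[str, str]  # peptide -> credited protein id
    credited_counts: dict[str, int]
    indistinguishable_groups: list[frozenset]
    unexplained: set[str]
    ambiguous: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def unique_credited(self, incidence: IncidenceMap) -> dict[str, int]:
        """Per-protein count of credited peptides that are unique to it."""
        counts: dict[str, int] = {pid: 0 for pid in self.accepted}
        for pep, pid in self.assignment.items():
            if incidence.peptides[pep] == frozenset({pid}):
                counts[pid] += 1
        return counts


@dataclass(frozen=True)
class FdrEstimate:
    n_target_accepted: int
    n_decoy_accepted: int
    fdr: float


def filter_evidence(
    observations: Sequence[PeptideObservation],
    incidence: IncidenceMap,
    config: PsmFilterConfig = PsmFilterConfig(),
) -> IncidenceMap:
    """Apply PSM and protein-level acceptance filters.

    Observations failing the ppm (inclusive) or probability (strict)
    thresholds are removed; proteins left with fewer than
    ``min_peptides`` distinct peptides are struck from every peptide's
    protein set, iterated to a fixed point.  Peptides losing all their
    proteins remain as orphans.  The operation is idempotent.
    """
    kept: dict[str, int] = {}
    for obs in observations:
        if abs(obs.ppm_error) > config.max_ppm:
            continue
        if obs.probability <= config.min_probability:
            continue
        kept[obs.sequence] = kept.get(obs.sequence, 0) + obs.spectra_count

    peptides = {
        pep: ids for pep, ids in incidence.peptides.items() if pep in kept
    }
    while True:
        counts: dict[str, int] = {}
        for ids in peptides.values():
            for pid in ids:
                counts[pid] = counts.get(pid, 0) + 1
        weak = {pid for pid, n in counts.items() if n < config.min_peptides}
        if not weak:
            break
        peptides = {
            pep: frozenset(ids - weak) for pep, ids in peptides.items()
        }
    return IncidenceMap(
        spot_id=incidence.spot_id,
        peptides=peptides,
        spectra={pep: kept[pep] for pep in peptides},
    )


def _indistinguishable_groups(incidence: IncidenceMap) -> list[frozenset]:
    by_pepset: dict[frozenset, list[str]] = {}
    for pid in sorted(incidence.proteins()):
        pepset = frozenset(incidence.peptides_of(pid))
        by_pepset.setdefault(pepset, []).append(pid)
    return [frozenset(g) for g in by_pepset.values() if len(g) > 1]


def _predominant(credited: Mapping[str, int]) -> Optional[str]:
    total = sum(credited.values())
    if not total:
        return None
    best = max(sorted(credited), key=lambda pid: credited[pid])
    return best if credited[best] * 2 > total else None


def greedy_assign(
    incidence: IncidenceMap, tie_break=None
) -> InferenceResult:
    """Scaffold-style greedy peptide assignment.

    Iteratively picks the protein matching the most unassigned peptides
    (ties by ``tie_break``, default lexicographic id) and credits it
    with all of them, shared included; repeats until no mappable
    peptide remains.
    """
    tie_break = tie_break or (lambda pid: pid)
    remaining = {p for p in incidence.peptides if incidence.peptides[p]}
    accepted: list[str] = []
    assignment: dict[str, str] = {}
    while remaining:
        candidates = sorted(
            {pid for pep in remaining for pid in incidence.peptides[pep]},
            key=tie_break,
        )
        best = max(
            candidates,
            key=lambda pid: len(
                {p for p in remaining if pid in incidence.peptides[p]}
            ),
        )
        taken = {p for p in remaining if best in incidence.peptides[p]}
        for pep in sorted(taken):
            assignment[pep] = best
        accepted.append(best)
        remaining -= taken
    credited: dict[str, int] = {pid: 0 for pid in accepted}
    for pid in assignment.values():
        credited[pid] += 1
    return InferenceResult(
        spot_id=incidence.spot_id,
        mode="greedy",
        accepted=accepted,
        predominant=_predominant(credited),
        assignment=assignment,
        credited_counts=credited,
        indistinguishable_groups=_indistinguishable_groups(incidence),
        unexplained=incidence.orphans(),
    )


def _cover_key(
    subset: Sequence[str],
    incidence: IncidenceMap,
    cultivar_specific: frozenset,
) -> tuple:
    n_cultivar = sum(1 for pid in subset if pid in cultivar_specific)
    unique_covered = sum(
        1
        for pep, ids in incidence.peptides.items()
        if len(ids) == 1 and next(iter(ids)) in subset
    )
    return (len(subset), -n_cultivar, -unique_covered, tuple(sorted(subset)))


def parsimony_assign(
    incidence: IncidenceMap,
    cultivar_specific: Iterable[str] = (),
    exact_limit: int = 20,
) -> InferenceResult:
    """Preference-minimal set cover of the spot's mappable peptides.

    For up to ``exact_limit`` candidate proteins the minimal cover is
    found exactly (smallest covers enumerated in increasing size);
    beyond that a greedy set-cover approximation is used and a warning
    logged.  Shared peptides are credited to the accepted protein that
    also owns at least one unique peptide, preferring more unique
    peptides, then cultivar-specific sequences, then lexicographic id;
    when several qualify the ambiguity is recorded.
    """
    cultivar = frozenset(cultivar_specific)
    mappable = {p for p, ids in incidence.peptides.items() if ids}
    candidates = sorted(incidence.proteins())

    accepted: list[str]
    if not mappable:
        accepted = []
    elif len(candidates) <= exact_limit:
        accepted = _exact_cover(incidence, candidates, mappable, cultivar)
    else:
        logger.warning(
            "spot %s: %d candidate proteins exceed exact-search limit %d; "
            "using greedy set cover",
            incidence.spot_id, len(candidates), exact_limit,
        )
        accepted = _greedy_cover(incidence, mappable)

    # indistinguishable proteins: collapse to one representative in the
    # accepted list (the lexicographically smallest was chosen by the key)
    groups = _indistinguishable_groups(incidence)

    unique_count = {
        pid: sum(
            1 for pep, ids in incidence.peptides.items()
            if ids == frozenset({pid})
        )
        for pid in accepted
    }
    # preference order for shared-peptide crediting
    def credit_rank(pid: str) -> tuple:
        return (-unique_count[pid], 0 if pid in cultivar else 1, pid)

    assignment: dict[str, str] = {}
    ambiguous: dict[str, tuple[str, ...]] = {}
    for pep in sorted(mappable):
        owners = [pid for pid in accepted if pid in incidence.peptides[pep]]
        if len(owners) == 1:
            assignment[pep] = owners[0]
            continue
        qualified = [pid for pid in owners if unique_count[pid] > 0]
        pool = qualified or owners
        pool = sorted(pool, key=credit_rank)
        assignment[pep] = pool[0]
        if len(pool) > 1:
            ambiguous[pep] = tuple(pool)

    credited: dict[str, int] = {pid: 0 for pid in accepted}
    for pid in assignment.values():
        credited[pid] += 1
    return InferenceResult(
        spot_id=incidence.spot_id,
        mode="parsimony",
        accepted=sorted(accepted, key=credit_rank),
        predominant=_predominant(credited),
        assignment=assignment,
        credited_counts=credited,
        indistinguishable_groups=groups,
        unexplained=incidence.orphans(),
        ambiguous=ambiguous,
    )


def _exact_cover(
    incidence: IncidenceMap,
    candidates: list[str],
    mappable: set[str],
    cultivar: frozenset,
) -> list[str]:
    pepsets = {pid: incidence.peptides_of(pid) & mappable for pid in candidates}
    for size in range(1, len(candidates) + 1):
        best: Optional[tuple] = None
        best_subset: Optional[tuple] = None
        for subset in itertools.combinations(candidates, size):
            covered: set[str] = set()
            for pid in subset:
                covered |= pepsets[pid]
            if covered != mappable:
                continue
            key = _cover_key(subset, incidence, cultivar)
            if best is None or key < best:
                best, best_subset = key, subset
        if best_subset is not None:
            return list(best_subset)
    raise AssertionError("mappable peptides must be coverable by candidates")


def _greedy_cover(incidence: IncidenceMap, mappable: set[str]) -> list[str]:
    remaining = set(mappable)
    accepted: list[str] = []
    while remaining:
        best = max(
            sorted(incidence.proteins()),
            key=lambda pid: len(incidence.peptides_of(pid) & remaining),
        )
        gain = incidence.peptides_of(best) & remaining
        if not gain:
            break
        accepted.append(best)
        remaining -= gain
    return accepted


def infer_spots(
    evidence: Mapping[str, Sequence[PeptideObservation]],
    db: SequenceDatabase,
    mode: str = "parsimony",
    scope: str = "per_spot",
    filter_config: PsmFilterConfig = PsmFilterConfig(),
    il_equivalent: bool = False,
) -> dict:
    """Run inference over a collection of spots.

    ``scope="per_spot"`` analyses each spot independently (the approach
    that resolves homologs best); ``scope="pooled"`` unions all spots'
    incidence first, infers once, and back-projects the accepted
    proteins onto each spot.  Returns ``{"results": {spot: result},
    "histogram": (n1, n2, n3plus)}`` counting spots by number of
    accepted proteins.
    """
    if not evidence:
        raise ValueError("no spots")
    if mode not in {"greedy", "parsimony"}:
        raise ValueError(f"unknown mode {mode!r}")
    if scope not in {"per_spot", "pooled"}:
        raise ValueError(f"unknown scope {scope!r}")
    cultivar = frozenset(
        rec.id for rec in db if rec.cultivar_specific and not rec.is_decoy
    )

    def run(inc: IncidenceMap) -> InferenceResult:
        if mode == "greedy":
            return greedy_assign(inc)
        return parsimony_assign(inc, cultivar_specific=cultivar)

    results: dict[str, InferenceResult] = {}
    if scope == "per_spot":
        for spot_id in sorted(evidence):
            inc = build_incidence(evidence[spot_id], db, il_equivalent)
            results[spot_id] = run(filter_evidence(evidence[spot_id], inc, filter_config))
    else:
        pooled_obs = [
            PeptideObservation(
                spot_id="__pooled__",
                protease=o.protease,
                sequence=o.sequence,
                spectra_count=o.spectra_count,
                ppm_error=o.ppm_error,
                probability=o.probability,
            )
            for spot_obs in evidence.values()
            for o in spot_obs
        ]
        pooled_inc = build_incidence(pooled_obs, db, il_equivalent)
        pooled_res = run(filter_evidence(pooled_obs, pooled_inc, filter_config))
        pooled_accept = set(pooled_res.accepted)
        for spot_id in sorted(evidence):
            inc = build_incidence(evidence[spot_id], db, il_equivalent)
            inc = filter_evidence(evidence[spot_id], inc, filter_config)
            spot_accept = sorted(
                pid for pid in pooled_accept if inc.peptides_of(pid)
            )
            assignment = {
                pep: pooled_res.assignment[pep]
                for pep in inc.peptides
                if pep in pooled_res.assignment
                and pooled_res.assignment[pep] in spot_accept
            }
            credited: dict[str, int] = {pid: 0 for pid in spot_accept}
            for pid in assignment.values():
                credited[pid] += 1
            results[spot_id] = InferenceResult(
                spot_id=spot_id,
                mode=mode,
                accepted=spot_accept,
                predominant=_predominant(credited),
                assignment=assignment,
                credited_counts=credited,
                indistinguishable_groups=pooled_res.indistinguishable_groups,
                unexplained=inc.orphans(),
            )

    hist = [0, 0, 0]
    for res in results.values():
        n = len(res.accepted)
        if n == 1:
            hist[0] += 1
        elif n == 2:
            hist[1] += 1
        elif n >= 3:
            hist[2] += 1
    return {"results": results, "histogram": tuple(hist)}


def estimate_fdr(accepted_ids: Iterable[str], db: SequenceDatabase) -> FdrEstimate:
    """Target-decoy false-discovery estimate: decoys / targets accepted."""
    n_target = n_decoy = 0
    for pid in accepted_ids:
        if db[pid].is_decoy:
            n_decoy += 1
        else:
            n_target += 1
    if n_target == 0 and n_decoy > 0:
        warnings.warn("no targets accepted but decoys present; FDR undefined")
        return FdrEstimate(0, n_decoy, math.inf)
    fdr = n_decoy / n_target if n_target else 0.0
    return FdrEstimate(n_target, n_decoy, fdr)
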