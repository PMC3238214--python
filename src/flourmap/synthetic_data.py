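"""Synthetic flour-proteome data with known ground truth.

Wet-lab 2-DE/MS-MS inputs for this kind of analysis are not
re-creatable, so every pipeline stage is exercised against generated
data that reproduces the *structure* of the real problem:

* families of near-identical Gln/Pro-rich, Lys/Arg-poor paralogs built
  from shared repeat blocks plus per-paralog divergent domains (the
  prolamin storage-protein situation that makes inference hard);
* spots containing one to a few proteins whose digests yield both
  shared and unique peptides, plus contaminant peptides;
* charge trains -- one protein spread over several spots;
* replicate gels with multiplicative (lognormal) volume noise.

What the generator does NOT emulate: real spectra, retention times,
deamidation-driven pI shifts (trains are split by a plain Dirichlet
draw), or the actual allele content of any cultivar.  A green
end-to-end test therefore establishes that the inference and
quantification arithmetic is correct on data with this structure, not
that any biological identification is right.

Everything is deterministic per seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .digestion import DigestConfig, ProteaseRule, builtin_rules, digest
from .peptide_mapping import PeptideObservation
from .quantification import GelSpotTable
from .sequence_db import ProteinRecord

# Background residue frequencies loosely matching wheat prolamins
# (Gln/Pro-rich, Lys/Arg-poor) used for divergent domains and
# contaminant peptides.  Includes enough F/Y/L/K/R that every protease
# finds cleavage sites.
_RESIDUES = np.array(list("QPGSFYLVAITEKRNHWD"))
_FREQS = np.array(
    [0.24, 0.14, 0.06, 0.06, 0.06, 0.05, 0.09, 0.05, 0.05, 0.04,
     0.04, 0.03, 0.015, 0.015, 0.03, 0.02, 0.01, 0.02]
)
_FREQS = _FREQS / _FREQS.sum()


@dataclass(frozen=True)
class FamilySpec:
    """How to build one paralog family.

    Defaults describe a typical gliadin-like situation: a handful of
    paralogs, repetitive Gln/Pro-rich backbone, ~2% point divergence,
    about 3% K+R, and 40% of members flagged cultivar-specific.
    """

    n_paralogs: int = 5
    repeat_motifs: tuple[str, ...] = ("PQQPFPQQ", "QQPYPQQ", "QPQQPFPW")
    repeat_count_range: tuple[int, int] = (8, 15)
    n_unique_domain_len: int = 60
    substitution_rate: float = 0.02
    indel_rate: float = 0.005
    kr_density: float = 0.03
    cultivar_fraction: float = 0.4
    family: str = "alpha-gliadin"
    id_prefix: str = "SYN"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_paralogs < 1:
            raise ValueError("n_paralogs must be >= 1")
        for r in (self.substitution_rate, self.indel_rate,
                  self.cultivar_fraction):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must lie in [0,1]")
        if not 0.0 <= self.kr_density <= 0.5:
            raise ValueError(
                "kr_density outside [0, 0.5]: not achievable for a "
                "prolamin-like family"
            )


@dataclass(frozen=True)
class DetectionModel:
    """How theoretical peptides turn into observed evidence."""

    detect_prob: float = 0.6
    per_protease: Mapping[str, float] = field(default_factory=dict)
    shared_vs_unique_ratio: float = 1.0
    contaminant_rate: float = 0.05  # expected contaminants per true peptide
    ppm_sigma: float = 20.0
    true_prob_range: tuple[float, float] = (0.95, 1.0)
    seed: int = 0

    def prob_for(self, protease: str) -> float:
        return float(self.per_protease.get(protease, self.detect_prob))


@dataclass(frozen=True)
class AbundanceModel:
    """Protein abundances, charge-train splitting and replicate noise."""

    dirichlet_concentration: float = 1.0
    mean_spots_per_protein: float = 8.0
    # chance a spot hosts a second, co-separating protein: roughly half of
    # real identified spots contain more than one protein
    cosep_prob: float = 0.35
    replicate_cv: float = 0.1
    n_replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_replicates < 2:
            raise ValueError("n_replicates must be >= 2")
        if self.replicate_cv < 0:
            raise ValueError("replicate_cv must be >= 0")


@dataclass
class GroundTruth:
    """What the generator actually put into the data."""

    spot_proteins: dict[str, frozenset]  # spot id -> true protein ids
    abundance: dict[str, float]  # protein id -> share of total (sums to 1)
    family_of: dict[str, str]
    contaminants: set[str] = field(default_factory=set)  # peptide sequences


# --- family generation ------------------------------------------------------


def _mutate(seq: str, spec: FamilySpec, rng: np.random.Generator) -> str:
    out: list[str] = []
    for aa in seq:
        r = rng.random()
        if r < spec.indel_rate / 2:
            continue  # deletion
        if r < spec.indel_rate:
            out.append(str(rng.choice(_RESIDUES, p=_FREQS)))  # insertion
        if rng.random() < spec.substitution_rate:
            out.append(str(rng.choice(_RESIDUES, p=_FREQS)))
        else:
            out.append(aa)
    return "".join(out) or seq[:1]


def _adjust_kr(seq: str, target: float, rng: np.random.Generator) -> str:
    """Nudge the K+R fraction to within +/-0.02 of target."""
    chars = list(seq)
    n = len(chars)
    def density() -> float:
        return sum(1 for c in chars if c in "KR") / n
    guard = 0
    while abs(density() - target) > 0.02:
        guard += 1
        if guard > 10 * n:
            raise ValueError("cannot reach requested kr_density")
        if density() < target:
            idx = [i for i, c in enumerate(chars) if c not in "KR"]
            chars[rng.choice(idx)] = "K" if rng.random() < 0.5 else "R"
        else:
            idx = [i for i, c in enumerate(chars) if c in "KR"]
            chars[rng.choice(idx)] = "Q"
    return "".join(chars)


def gen_family(spec: FamilySpec) -> tuple[list[ProteinRecord], GroundTruth]:
    """Build one family of prolamin-like paralogs.

    All paralogs share a mutated copy of the same repeat backbone (the
    source of shared peptides) and each carries its own divergent
    domain (the source of unique peptides).
    """
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.repeat_count_range
    n_blocks = int(rng.integers(lo, hi + 1))
    backbone = "".join(
        spec.repeat_motifs[i % len(spec.repeat_motifs)] for i in range(n_blocks)
    )
    records: list[ProteinRecord] = []
    n_cultivar = round(spec.cultivar_fraction * spec.n_paralogs)
    for k in range(spec.n_paralogs):
        shared = _mutate(backbone, spec, rng) if spec.n_paralogs > 1 else backbone
        if spec.substitution_rate == 0 and spec.indel_rate == 0:
            shared = backbone
        unique = "".join(
            rng.choice(_RESIDUES, p=_FREQS, size=spec.n_unique_domain_len)
        )
        seq = _adjust_kr(shared + unique, spec.kr_density, rng)
        records.append(
            ProteinRecord(
                id=f"{spec.id_prefix}{k + 1:02d}",
                sequence=seq,
                family=spec.family,
                cultivar_specific=k < n_cultivar,
                description="synthetic paralog",
            )
        )
    truth = GroundTruth(
        spot_proteins={},
        abundance={},
        family_of={r.id: r.family for r in records},
    )
    return records, truth


# --- spot structure / charge trains ----------------------------------------


def assign_spots(
    records: Sequence[ProteinRecord],
    abundance: AbundanceModel,
) -> GroundTruth:
    """Draw abundances and split each protein over its charge train.

    Each protein gets ``1 + Poisson(mean - 1)`` spots; optionally a
    spot may also host a second, minor co-separating protein.
    """
    rng = np.random.default_rng(abundance.seed)
    ids = [r.id for r in records]
    shares = rng.dirichlet(
        [abundance.dirichlet_concentration] * len(ids)
    )
    truth = GroundTruth(
        spot_proteins={},
        abundance={pid: float(s) for pid, s in zip(ids, shares)},
        family_of={r.id: r.family for r in records},
    )
    spot_n = 0
    for pid in ids:
        k = 1 + int(rng.poisson(max(abundance.mean_spots_per_protein - 1, 0)))
        for _ in range(k):
            spot_n += 1
            members = {pid}
            if abundance.cosep_prob and rng.random() < abundance.cosep_prob:
                other = str(rng.choice([i for i in ids if i != pid])) if len(ids) > 1 else None
                if other:
                    members.add(other)
            truth.spot_proteins[f"spot{spot_n:03d}"] = frozenset(members)
    return truth


# --- evidence ---------------------------------------------------------------


def _theoretical_peptides(
    record: ProteinRecord,
    rules: Mapping[str, ProteaseRule],
    config: DigestConfig,
) -> dict[str, set[str]]:
    return {
        name: {f.sequence for f in digest(record.sequence, rule, config, record.id)}
        for name, rule in rules.items()
    }


def gen_spot_evidence(
    records: Sequence[ProteinRecord],
    truth: GroundTruth,
    detection: DetectionModel = DetectionModel(),
    digest_config: DigestConfig = DigestConfig(),
    rules: Optional[Mapping[str, ProteaseRule]] = None,
) -> list[PeptideObservation]:
    """Sample per-spot peptide observations from the theoretical digests.

    Every bounds-passing theoretical peptide of a spot's true proteins
    is detected independently with the per-protease probability
    (down-weighted for peptides shared between several records when
    ``shared_vs_unique_ratio`` < 1); contaminant peptides are random
    prolamin-like strings verified absent from all target sequences.
    """
    rules = dict(rules or builtin_rules())
    rng = np.random.default_rng(detection.seed)
    by_record = {r.id: _theoretical_peptides(r, rules, digest_config) for r in records}
    occurrence: dict[str, int] = {}
    for pep_by_rule in by_record.values():
        for peps in pep_by_rule.values():
            for pep in peps:
                occurrence[pep] = occurrence.get(pep, 0) + 1
    target_seqs = [r.sequence for r in records]

    lo, hi = detection.true_prob_range
    observations: list[PeptideObservation] = []
    for spot_id in sorted(truth.spot_proteins):
        n_true = 0
        spot_peps: dict[str, str] = {}  # peptide -> protease
        for pid in sorted(truth.spot_proteins[spot_id]):
            for protease in sorted(rules):
                p = detection.prob_for(protease)
                for pep in sorted(by_record[pid][protease]):
                    if pep in spot_peps:
                        continue
                    p_eff = p
                    if occurrence.get(pep, 0) > 1:
                        p_eff = min(1.0, p * detection.shared_vs_unique_ratio)
                    if rng.random() < p_eff:
                        spot_peps[pep] = protease
        for pep, protease in sorted(spot_peps.items()):
            n_true += 1
            observations.append(
                PeptideObservation(
                    spot_id=spot_id,
                    protease=protease,
                    sequence=pep,
                    spectra_count=1,
                    ppm_error=float(rng.normal(0.0, detection.ppm_sigma)),
                    probability=float(rng.uniform(lo, hi)),
                )
            )
        n_contam = int(rng.poisson(detection.contaminant_rate * n_true))
        for _ in range(n_contam):
            pep = _contaminant_peptide(rng, target_seqs)
            truth.contaminants.add(pep)
            observations.append(
                PeptideObservation(
                    spot_id=spot_id,
                    protease=str(rng.choice(sorted(rules))),
                    sequence=pep,
                    spectra_count=1,
                    ppm_error=float(rng.normal(0.0, detection.ppm_sigma)),
                    probability=float(rng.uniform(0.0, 1.0)),
                )
            )
    return observations


def _contaminant_peptide(
    rng: np.random.Generator, target_seqs: Sequence[str]
) -> str:
    for _ in range(100):
        length = int(rng.integers(7, 21))
        pep = "".join(rng.choice(_RESIDUES, p=_FREQS, size=length))
        if not any(pep in seq for seq in target_seqs):
            return pep
    raise RuntimeError("could not draw a contaminant absent from all targets")


# --- volumes ----------------------------------------------------------------


def gen_volumes(
    truth: GroundTruth, abundance: AbundanceModel = AbundanceModel()
) -> list[GelSpotTable]:
    """Replicate gels of raw spot volumes.

    Each protein's abundance is split over the spots containing it by a
    symmetric Dirichlet draw; each gel multiplies every spot by
    lognormal noise with the requested coefficient of variation.
    """
    rng = np.random.default_rng(abundance.seed + 1)
    spots = sorted(truth.spot_proteins)
    spots_of: dict[str, list[str]] = {}
    for spot in spots:
        for pid in sorted(truth.spot_proteins[spot]):
            spots_of.setdefault(pid, []).append(spot)
    base: dict[str, float] = {spot: 0.0 for spot in spots}
    for pid in sorted(spots_of):
        member_spots = spots_of[pid]
        split = rng.dirichlet([1.0] * len(member_spots))
        for spot, frac in zip(member_spots, split):
            base[spot] += truth.abundance.get(pid, 0.0) * float(frac)
    cv = abundance.replicate_cv
    sigma = math.sqrt(math.log(1.0 + cv * cv)) if cv > 0 else 0.0
    gels: list[GelSpotTable] = []
    for g in range(abundance.n_replicates):
        vols = {}
        for spot in spots:
            noise = math.exp(rng.normal(-sigma * sigma / 2, sigma)) if sigma else 1.0
            vols[spot] = base[spot] * noise
        gels.append(GelSpotTable(gel_id=f"gel{g + 1}", volumes=vols))
    return gels


# --- evaluation -------------------------------------------------------------


def evaluate_recovery(
    results: Mapping[str, "InferenceResult"],
    truth: GroundTruth,
    protein_volume_estimates: Optional[Mapping[str, float]] = None,
) -> dict:
    """Score inference (and optionally quantification) against truth.

    Per-spot precision/recall of accepted protein sets, the fraction of
    spots recovered exactly, and -- when per-protein volume estimates on
    the 0-1 scale are supplied -- mean absolute abundance error.
    """
    per_spot: dict[str, dict] = {}
    for spot, res in results.items():
        true_set = set(truth.spot_proteins.get(spot, frozenset()))
        got = set(res.accepted)
        tp = len(got & true_set)
        precision = tp / len(got) if got else (1.0 if not true_set else 0.0)
        recall = tp / len(true_set) if true_set else 1.0
        per_spot[spot] = {
            "precision": precision,
            "recall": recall,
            "exact": got == true_set,
        }
    n = len(per_spot)
    metrics = {
        "per_spot": per_spot,
        "mean_precision": sum(v["precision"] for v in per_spot.values()) / n if n else 0.0,
        "mean_recall": sum(v["recall"] for v in per_spot.values()) / n if n else 0.0,
        "fraction_exact": sum(v["exact"] for v in per_spot.values()) / n if n else 0.0,
    }
    if protein_volume_estimates is not None:
        errs = [
            abs(protein_volume_estimates.get(pid, 0.0) - share)
            for pid, share in truth.abundance.items()
        ]
        metrics["abundance_mae"] = sum(errs) / len(errs) if errs else 0.0
    return metrics
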