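"""In-silico protease digestion.

Wheat prolamins are poor in Lys/Arg, so trypsin alone leaves much of a
storage protein unobserved; digesting separately with trypsin,
chymotrypsin and thermolysin and pooling the peptides is what makes
these proteins identifiable.  This module generates the theoretical
peptides for each protease, with missed cleavages, optional
semi-specific termini (which model processed N-termini such as the
SHIP/MET forms arising from in vivo proteolysis), peptide masses with
optional deamidation, and sequence-coverage statistics.

Cleavage rules are declared, versioned constants:

* trypsin -- C-terminal to K or R, blocked when the next residue is P;
* chymotrypsin -- C-terminal to F, Y, W or L, blocked by P (M excluded
  by default, configurable by registering a custom rule);
* thermolysin -- N-terminal to A, F, I, L, M or V, no exceptions.

Coordinates are 1-based inclusive residue positions throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

from . import chem


@dataclass(frozen=True)
class ProteaseRule:
    """Cleavage specificity of one protease.

    ``side`` is the side of the recognized residue on which the bond is
    cut: "C" cleaves after a residue in ``cut_residues``, "N" before.
    ``blocked_next`` suppresses cleavage when the residue following the
    cut site is in the set (the classic proline block).
    """

    name: str
    cut_residues: frozenset
    side: str  # "C" or "N"
    blocked_next: frozenset = frozenset()

    def __post_init__(self) -> None:
        if not self.cut_residues:
            raise ValueError(f"rule {self.name!r}: empty cut set")
        if self.side not in {"C", "N"}:
            raise ValueError(f"rule {self.name!r}: side must be 'C' or 'N'")

    def cleavage_sites(self, sequence: str) -> list[int]:
        """Cut points as indices into the inter-residue gaps (0..len)."""
        n = len(sequence)
        sites = [0]
        for i in range(1, n):
            # a cut between sequence[i-1] and sequence[i]
            if self.side == "C":
                ok = sequence[i - 1] in self.cut_residues and (
                    sequence[i] not in self.blocked_next
                )
            else:
                ok = sequence[i] in self.cut_residues and (
                    sequence[i] not in self.blocked_next
                )
            if ok:
                sites.append(i)
        sites.append(n)
        return sites


def builtin_rules() -> dict[str, ProteaseRule]:
    """Registry of the three proteases used for flour-protein digests."""
    rules = [
        ProteaseRule("trypsin", frozenset("KR"), "C", frozenset("P")),
        ProteaseRule("chymotrypsin", frozenset("FYWL"), "C", frozenset("P")),
        ProteaseRule("thermolysin", frozenset("AFILMV"), "N"),
    ]
    return {r.name: r for r in rules}


def get_rule(name: str) -> ProteaseRule:
    registry = builtin_rules()
    if name not in registry:
        raise KeyError(f"unknown protease {name!r}; have {sorted(registry)}")
    return registry[name]


@dataclass(frozen=True)
class DigestConfig:
    """Bounds and specificity for a digest.

    Defaults reflect what a QTOF-style LC-MS/MS run can observe: 5-60
    residues, 400-6000 Da, up to two missed cleavages.
    """

    max_missed: int = 2
    min_len: int = 5
    max_len: int = 60
    min_mass: float = 400.0
    max_mass: float = 6000.0
    specificity: str = "full"  # full | semi_n | semi_c | semi_both
    variable_deamidation: bool = False

    def __post_init__(self) -> None:
        if self.max_missed < 0:
            raise ValueError("max_missed must be >= 0")
        if self.min_len > self.max_len or self.min_mass > self.max_mass:
            raise ValueError("min bound exceeds max bound")
        if self.specificity not in {"full", "semi_n", "semi_c", "semi_both"}:
            raise ValueError(f"unknown specificity {self.specificity!r}")


UNFILTERED = DigestConfig(
    max_missed=0, min_len=1, max_len=10**9, min_mass=0.0, max_mass=float("inf")
)


@dataclass(frozen=True)
class PeptideFragment:
    """One theoretical peptide; start/end are 1-based inclusive."""

    parent_id: str
    start: int
    end: int
    sequence: str
    n_missed: int
    specificity_class: str  # full | semi
    mass_mono: float


def _fragment(parent_id: str, sequence: str, start0: int, end0: int,
              n_missed: int, spec_class: str) -> PeptideFragment:
    sub = sequence[start0:end0]
    return PeptideFragment(
        parent_id=parent_id,
        start=start0 + 1,
        end=end0,
        sequence=sub,
        n_missed=n_missed,
        specificity_class=spec_class,
        mass_mono=chem.molecular_weight(sub, "monoisotopic"),
    )


def digest(
    sequence: str,
    rule: ProteaseRule,
    config: DigestConfig = DigestConfig(),
    parent_id: str = "",
) -> list[PeptideFragment]:
    """Theoretical peptides of one protease digest.

    Full-specificity fragments span consecutive cleavage sites with at
    most ``max_missed`` internal sites; the semi modes add fragments
    with one ragged terminus (the other anchored at a cleavage site).
    Output is filtered by the length/mass bounds and sorted by
    (start, end).  'X'-containing fragments are silently skipped since
    they have no defined mass.
    """
    sites = rule.cleavage_sites(sequence)
    site_set = set(sites)
    seen: set[tuple[int, int]] = set()
    out: list[PeptideFragment] = []

    def missed_inside(start0: int, end0: int) -> int:
        return sum(1 for s in sites if start0 < s < end0)

    def emit(start0: int, end0: int, n_missed: int, spec_class: str) -> None:
        if (start0, end0) in seen:
            return
        seen.add((start0, end0))
        length = end0 - start0
        if not (config.min_len <= length <= config.max_len):
            return
        sub = sequence[start0:end0]
        if "X" in sub:
            return
        frag = _fragment(parent_id, sequence, start0, end0, n_missed, spec_class)
        if config.min_mass <= frag.mass_mono <= config.max_mass:
            out.append(frag)

    for i in range(len(sites) - 1):
        for j in range(i + 1, min(i + 2 + config.max_missed, len(sites))):
            start0, end0 = sites[i], sites[j]
            n_missed = j - i - 1
            emit(start0, end0, n_missed, "full")
            if config.specificity in {"semi_n", "semi_both"}:
                # ragged N-terminus, C-terminus kept at a cleavage site
                for s in range(start0 + 1, end0):
                    if s not in site_set:
                        emit(s, end0, missed_inside(s, end0), "semi")
            if config.specificity in {"semi_c", "semi_both"}:
                for e in range(start0 + 1, end0):
                    if e not in site_set:
                        emit(start0, e, missed_inside(start0, e), "semi")

    out.sort(key=lambda f: (f.start, f.end))
    return out


def peptide_mass(
    fragment: PeptideFragment | str, deamidated_positions: Iterable[int] = ()
) -> float:
    """Monoisotopic peptide mass, each deamidation adding +0.98402 Da.

    Deamidation positions are 1-based indices into the peptide and must
    point at N or Q residues.
    """
    seq = fragment if isinstance(fragment, str) else fragment.sequence
    mass = chem.molecular_weight(seq, "monoisotopic")
    for pos in deamidated_positions:
        if not 1 <= pos <= len(seq) or seq[pos - 1] not in "NQ":
            raise ValueError(
                f"deamidation position {pos} does not index an N or Q residue"
            )
        mass += chem.DEAMIDATION_SHIFT
    return mass


def coverage(parent_length: int, fragments: Sequence[PeptideFragment]) -> float:
    """Fraction of parent residues covered by the union of fragments."""
    if parent_length <= 0:
        raise ValueError("parent_length must be positive")
    intervals = []
    for f in fragments:
        if f.start < 1 or f.end > parent_length:
            raise ValueError(
                f"fragment {f.start}-{f.end} outside 1..{parent_length}"
            )
        intervals.append((f.start, f.end))
    if not intervals:
        return 0.0
    intervals.sort()
    covered = 0
    cur_start, cur_end = intervals[0]
    for s, e in intervals[1:]:
        if s <= cur_end + 1:
            cur_end = max(cur_end, e)
        else:
            covered += cur_end - cur_start + 1
            cur_start, cur_end = s, e
    covered += cur_end - cur_start + 1
    return covered / parent_length


def multi_protease_coverage(
    sequence: str,
    rules: Iterable[ProteaseRule],
    config: DigestConfig = DigestConfig(),
    parent_id: str = "",
) -> dict:
    """Per-protease and pooled coverage of one sequence.

    Returns ``{"per_rule": {name: {"coverage", "n_fragments"}},
    "union_coverage": float}``; pooling the digests can only increase
    coverage, which is the point of the three-protease strategy.
    """
    rules = list(rules)
    if not rules:
        raise ValueError("need at least one protease rule")
    per_rule: dict[str, dict] = {}
    all_frags: list[PeptideFragment] = []
    for rule in rules:
        frags = digest(sequence, rule, config, parent_id)
        per_rule[rule.name] = {
            "coverage": coverage(len(sequence), frags),
            "n_fragments": len(frags),
        }
        all_frags.extend(frags)
    return {
        "per_rule": per_rule,
        "union_coverage": coverage(len(sequence), all_frags),
    }
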