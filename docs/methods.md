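# Methods

## Problem setting

Two-dimensional electrophoresis resolves a wheat-flour extract into a
few hundred spots; each spot is excised, digested separately with three
proteases, and the peptides identified by tandem MS. Identification of
the underlying proteins is hard for reasons intrinsic to cereal storage
proteins: paralogs within a family (and homoeologs across the A/B/D
genomes of hexaploid wheat) share long identical stretches, the
sequences are repetitive and Lys/Arg-poor, and a single protein forms a
charge train spanning several spots. This package implements the
downstream analysis — digestion modelling, peptide mapping, protein
inference, FDR, quantification — on peptide-level evidence; spectral
scoring and gel image analysis are upstream and out of scope
(peptide sequences, probabilities and spot volumes arrive as inputs).

## Masses and isoelectric points

Residue masses (average and monoisotopic) are embedded constants, and a
peptide/protein mass is the residue sum plus one water. Deamidation
(N→D, Q→E) adds +0.98402 Da per site, the mass step that explains
1-Da-spaced charge-train neighbours. The pI is the bisection root
(pH 0–14, tolerance 0.005) of the Henderson–Hasselbalch net charge over
the termini and D/E/C/Y/H/K/R side chains. The default pKa set is the
Bjellqvist table used by ProtParam-style tools; an EMBOSS-style set is
selectable. Because the exact historical pKa set behind any published
pI column is unknowable, small pI differences from printed tables are
expected and pI is not an acceptance surface. `X` residues are allowed
in stored sequences (partial contigs) but rejected by mass/pI
computations rather than guessed at.

## Digestion model

Cleavage rules are declared constants: trypsin cuts C-terminally to
K/R, chymotrypsin C-terminally to F/Y/W/L (the high-specificity set
plus Leu, matching observed Leu-terminal peptides; Met excluded by
default), both blocked by a following Pro; thermolysin cuts
N-terminally to A/F/I/L/M/V with no exceptions. The engines' 2010-era
definitions are unrecoverable, so the rules are versioned here and
cross-checked in tests against an independent regex statement of the
same chemistry. Default observable bounds: 5–60 residues, 400–6000 Da,
≤2 missed cleavages — a QTOF-style LC-MS/MS window. "Non-standard"
cleavages observed in vivo (SHIP-, MET-, KEL-type N-termini) are
modelled as semi-specific digestion (one ragged terminus) rather than
ad-hoc cut lists: one mechanism reproduces all observed forms.
Coordinates are 1-based inclusive.

## Peptide mapping

Mapping is exact substring search of the peptide in target sequences;
decoys are never reported by the default mapper (an `include_decoys`
switch would be needed only for bespoke decoy searches; the FDR
estimator takes accepted id lists from any source). I/L equivalence,
off by default because the catalogue's manual matching used literal
database sequences, folds L→I positionwise on both sides when enabled.
N-terminal processing forms are detected at declared offsets
(0 intact, 1 pyroglutamate-style Gln loss, 4 for QMEN→SHIP trimming,
8 for ARQL→KEL omega trimming); an observation is reported only where
it literally matches the mature sequence at that offset. Epitope
scanning is exact substring matching (overlaps allowed) with an
optional Q/E fold approximating transglutaminase deamidation; the
shipped motif library is an example fixture sourced from the celiac
literature, external to the spot catalogue.

## Protein inference

PSM filters follow the catalogue's stated thresholds verbatim: mass
error ≤ 100 ppm (inclusive), peptide probability > 0.90 (strict), and
≥2 distinct peptides per protein, applied to a fixed point (the
operation is idempotent; peptides stripped of all proteins remain as
reported orphans).

*Greedy* assignment reproduces the Scaffold-style behaviour: repeatedly
credit the protein matching the most unassigned peptides with all of
them (ties to the lexicographically smaller id). *Parsimony* selects
the preference-minimal cover of all mappable peptides — preference:
fewer proteins, then more cultivar-specific members, then more unique
peptides covered, then lexicographic ids. Covers are enumerated exactly
by increasing size for up to 20 candidate proteins (real spots carry a
handful); beyond that a greedy set cover is used and a warning logged.
Proteins with identical peptide sets are reported as one
indistinguishable group. Shared peptides are credited to the accepted
protein that also owns ≥1 unique peptide; when several qualify the
preference-first protein takes the peptide and the ambiguity is
recorded — counts are never split, so the dominant homolog's credited
count can exceed its unique count by design, mirroring the greedy
overstatement it is meant to expose. A spot's *predominant* protein
requires a strict majority of credited peptides; otherwise the spot is
labelled mixed and aggregated as its own category, never split.

FDR is the plain ratio decoys/targets accepted (not 2D/(T+D)): it
matches the way 0.0% results are reported and is monotone; the
alternative can be computed from the same `FdrEstimate` fields. Zero
targets with ≥1 decoy yields an infinity sentinel with a warning.

## Quantification

Per gel, spot volume is `raw / total × 100` (sums to 100 within 1e-9);
replicates contribute an arithmetic mean and sample SD, and a spot
missing from one gel counts as missing (n decremented), not zero — the
catalogue does not state its policy, and zero-filling would bias small
spots downward. Censored `"<0.01"` entries parse as 0.0 with a flag
(consistent with every printed group total; a 0.005 midpoint policy
would change totals by <0.01). `inc`/`nd`/`-` entries are missing, not
zero. Aggregation at any level (protein, family, locus, genome, celiac
class) is a plain sum of member-spot mean volumes, so volume is
conserved exactly; percent-of-parent ratios are computed at full
precision and rounded half-away-from-zero to one decimal only for
presentation. Locus and genome labels are annotation inputs transcribed
with the tables, not inferred from sequence. One catalogue spot appears
in two tables (once with a volume, once without); the volume-bearing
row is its assignment.

## Synthetic data

The generator states a world resembling the real catalogue rather than
a tunable benchmark: families of 5 paralogs built from a shared
Gln/Pro-rich repeat backbone (8–15 blocks) mutated at 2% substitution /
0.5% indel per residue, plus a 60-residue divergent domain per paralog;
K+R density adjusted to 3% ± 2%; 40% of members flagged
cultivar-specific. Each protein spreads over `1 + Poisson(7)` spots
(mean 8, the charge-train statistic of the HMW subunits) and ~35% of
spots host a second co-separating protein (about half of real
identified spots contain more than one protein). Evidence: every
bounds-passing theoretical peptide of a spot's proteins is detected
independently (default probability 0.6 per protease), true-peptide
probabilities are uniform on [0.95, 1] ("near 1"), mass errors normal
with σ = 20 ppm, and contaminant peptides are random prolamin-like
strings verified absent from all targets, with uniform probability
scores. Volumes: protein abundances from a flat Dirichlet, split over
each protein's spots by a symmetric Dirichlet, multiplied per gel by
lognormal noise with CV 0.1 over 3 replicates (gel volumes are
positive and right-skewed; printed SD/mean ratios are loosely of this
order). Everything is deterministic per seed.

What a green end-to-end test establishes: the inference and
quantification arithmetic recovers planted truth on data with the real
problem's *structure* (shared vs unique peptides, charge trains,
contaminants, replicate noise). It does not establish anything about
real spectra, retention behaviour, deamidation-driven pI shifts, or any
actual cultivar's allele content — none of which are modelled.

## Numerical choices and edge cases

* Bisection bracket pH 0–14; tolerance 0.005 pH.
* Digest output sorted by (start, end); deterministic across runs and
  independent of rule-registry order.
* Tie-breaks are lexicographic everywhere a preference does not decide.
* Empty digest results, empty epitope libraries, and all-orphan spots
  are valid inputs with empty outputs, not errors.
* Coverage of adjacent intervals counts their union of residues (no
  double counting; adjacency is not a gap).
* Seeds below 2³¹ throughout; the acceptance script reduces its seed
  modulo 2³¹.

## Known limitations

* The exact-cover search is exponential in candidate count; the default
  cap of 20 candidates is safe for spot-sized problems only.
* Probabilities are consumed, never modelled: there is no
  PeptideProphet-style rescoring.
* The fixture catalogue reproduces printed per-spot rows; its internal
  totals carry the source's own small inconsistencies (231 distinct
  spots listed vs a stated 233), which this package records rather than
  repairs.
* Epitope motifs ship as examples; any immunological use requires
  verifying the motifs against primary literature.
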