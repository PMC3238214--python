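"""Roll up the packaged spot catalogue to flour-composition numbers.

The packaged fixture tables carry 231 identified 2-DE spots of a wheat
flour proteome with their normalized volumes (percent of total gel
volume, mean of three replicate gels).  Aggregating them reproduces the
storage-protein composition of the flour.
"""

from flourmap import (
    aggregate,
    charge_trains,
    identified_summary,
    parse_catalogue_tables,
    round1,
    share_percent,
)

quants, assignment = parse_catalogue_tables()

summary = identified_summary(quants, assignment)
print(f"identified spots: {summary['n_identified']}, accounting for "
      f"{round1(summary['identified_volume'])}% of total spot volume\n")

fam = aggregate(quants, assignment, "family")
print("family totals (% of total flour protein):")
for name in sorted(fam.groups, key=lambda k: -fam.groups[k]["total"])[:6]:
    g = fam.groups[name]
    print(f"  {name:<16} {g['total']:6.2f}%  over {g['n_spots']} spots")

hmw = fam.groups["HMW-GS"]["total"]
prot = aggregate(quants, assignment, "protein", within_family="HMW-GS")
bx7 = prot.groups["HMW-GS Bx7"]["total"]
print(f"\nBx7 subunit: {round1(bx7)}% of flour protein = "
      f"{share_percent(bx7, hmw)}% of the HMW-GS fraction")

genome = aggregate(quants, assignment, "genome", within_family="HMW-GS")
print(f"A-genome share of HMW-GS: "
      f"{share_percent(genome.groups['A']['total'], hmw)}% "
      "(the A genome contributes far less than B or D)")

trains = charge_trains(assignment, quants, family="HMW-GS")
print(f"\nHMW-GS charge trains: {trains['n_spots']} spots from "
      f"{trains['n_proteins']} proteins = "
      f"{trains['mean_spots_per_protein']:.1f} spots/protein on average")
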