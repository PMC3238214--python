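"""Build an annotated sequence database, derive mature proteins, add decoys.

Storage-protein precursors carry an N-terminal signal peptide that is
removed in vivo; molecular weight and isoelectric point are therefore
computed from the mature (trimmed) sequence, which is what a 2-DE gel
actually resolves.
"""

from flourmap import (
    ProteinRecord,
    SequenceDatabase,
    build_subset,
    generate_decoys,
    trim_signal,
)

precursor = (
    "MKTFLVFALLAIVATTATTA"  # 20-residue signal peptide
    + "QMENSHIPGLERPSQQQPLPPQQTLSHHHQQQKVDQESRSHH"
)
db = SequenceDatabase([
    ProteinRecord(id="lmw_bu3", sequence=precursor, family="LMW-GS",
                  genome="B", cultivar_specific=True, signal_len=20),
    ProteinRecord(id="agli_bu5", sequence="VRVPVPQLQLQPFPQPQLSYSQPQPFRPQQPYPQPQPQY",
                  family="alpha-gliadin", genome="A", cultivar_specific=True),
])

mature = trim_signal(db["lmw_bu3"])
print(f"precursor length : {len(db['lmw_bu3'].sequence)} residues")
print(f"mature length    : {len(mature.mature_sequence)} residues")
print(f"mature MW        : {mature.mw_da / 1000:.1f} kDa")
print(f"mature pI        : {mature.pi:.2f}")
# The mature MW/pI are what to compare against the spot's gel position.

with_decoys = generate_decoys(db)
print(f"\nafter decoy generation: {with_decoys.n_targets} targets, "
      f"{with_decoys.n_decoys} decoys")

# Second-pass subset database: keep sequences scoring >= 20% in a first
# pass, then append an equal number of decoys.
subset = build_subset(db, {"lmw_bu3": 0.95, "agli_bu5": 0.05})
print(f"subset database: {subset.n_targets} target(s) retained at the 20% "
      f"threshold, {subset.n_decoys} decoy(s) appended")
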