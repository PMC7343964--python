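"""The reporter peptide's diagnostic ions and cross-link precursor masses.

Prints the CSEIWDR reporter's 10-ion fingerprint — the y ions of the
reporter chain, their ammonia-loss satellites, and the disulfide-cleavage
triplet (thiol MH+, persulfide MH+ +S, dehydroalanine MH+ -SH2) — and the
precursor mass of a cross-link with a partner peptide. A spectrum showing
all ten ions almost certainly fragments a reporter cross-link.
"""

from sulfenlink import crosslink_precursor_mass, mz_from_mass, reporter_diagnostic_ions, round_mz

fingerprint = reporter_diagnostic_ions()
print("CSEIWDR diagnostic-ion fingerprint (label, m/z):")
for label, mz in fingerprint.entries:
    print(f"  {label:>7}  {round_mz(mz):.4f}")

mass = crosslink_precursor_mass("CSEIWDR", "VIEYCK")
print(f"\nCSEIWDR x VIEYCK cross-link neutral mass: {round_mz(mass):.4f} Da")
print(f"  precursor m/z at 3+: {round_mz(mz_from_mass(mass, 3)):.4f}")
print("(neutral mass = chain masses summed minus two hydrogens for the disulfide)")
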