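"""Tryptic digestion and the reporter-isobaric conflict screen.

Digests a toy protein carrying the reporter context and shows the
missed-cleavage anchor variants; then screens a database whose reversed
decoy produces a CSELWDR peptide isobaric with the CSEIWDR reporter —
exactly the kind of segment that must be masked before decoy generation.
"""

from sulfenlink import ProteinRecord, digest, find_isobaric_reporter_conflicts

probe = ProteinRecord("PROBE", "reporter-bearing construct", "EGSLLRCSEIWDRITTHPK")
print("Tryptic peptides (<=1 missed cleavage) of", probe.sequence)
for p in digest(probe, max_missed=1, min_len=1, max_len=60):
    print(f"  {p.sequence:<15} residues {p.start}-{p.end}, {p.missed_cleavages} missed")

suspect = ProteinRecord("AT1", "protein ending in RDWLESC", "MAAAKGGGKRDWLESC")
print("\nReporter-isobaric screen of", suspect.sequence)
for c in find_isobaric_reporter_conflicts([suspect], "CSEIWDR"):
    print(" ", c.reason)
print("(the reversed tail reads CSELWDR; Leu/Ile are isobaric, so a decoy")
print(" search would soak up genuine reporter spectra without masking)")
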