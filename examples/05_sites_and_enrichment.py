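"""From cross-linked peptides to non-redundant sulfenylated-site calls.

Shows the redundancy collapse (missed-cleavage variants reporting the same
cysteine become one site), shared-peptide ambiguity resolution via
linear-peptide protein evidence, and a hypergeometric domain-enrichment
test on a toy background.
"""

import pandas as pd

from sulfenlink import ProteinRecord
from sulfenlink.sites import (
    CLPeptideObservation,
    collapse_redundant,
    domain_enrichment,
    resolve_ambiguity,
)

database = [
    ProteinRecord("IDH1", "isocitrate dehydrogenase-like", "MNNRCATITPDEGRVTEFGLKHHHK"),
    ProteinRecord("PP5L", "phosphatase-like", "MGGKLKECEKTTTRWWNPLK"),
    ProteinRecord("PPI2L", "pump-interactor-like", "MPPPFFRKLKECEKSSSK"),
]

obs = [
    CLPeptideObservation("CATITPDEGR", 1, {"ctrl": 3}),
    CLPeptideObservation("CATITPDEGRVTEFGLK", 1, {"h2o2": 2}),
    CLPeptideObservation("KLKECEK", 5, {"ctrl": 2}),
]
sites = collapse_redundant(obs, database)
print("non-redundant sites:")
for s in sites:
    amb = f" ambiguous across {s.ambiguous_proteins}" if s.ambiguous_proteins else ""
    print(
        f"  {s.protein_accession} Cys{s.cys_position}: representative "
        f"{s.representative_peptide}, {s.total_psms()} PSMs{amb}"
    )

evidence = {"PP5L": (23, 194), "PPI2L": (0, 0)}
chosen, flag = resolve_ambiguity(["PP5L", "PPI2L"], evidence)
print(f"\nKLKECEK ambiguity: prefer {chosen[0]} ({flag}; 23 vs 0 linear peptides)")

background = pd.DataFrame(
    [("IDH1", 5, "NADP-binding"), ("PP5L", 8, None), ("PPI2L", 12, None)],
    columns=["accession", "cys_position", "domain_label"],
)
table = domain_enrichment([("IDH1", 5), ("PP5L", 8)], background)
print("\ndomain enrichment (hypergeometric upper tail, BH-corrected):")
print(table.to_string(index=False))
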