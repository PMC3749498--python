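"""Screen for virus-to-cell horizontal gene transfers.

A cellular protein that (1) is a viral peptide's best cellular homolog and
(2) finds that viral peptide back as its own best hit - after masking
every subject sharing its first three lineage labels - is an HGT
candidate.  We plant two transfers and add unrelated decoys.
"""

import numpy as np

from ncldvscope.hgt import screen_hgt
from ncldvscope.model import ReferenceDB, ReferenceProtein, parse_lineage

rng = np.random.default_rng(13)
aa = list("ACDEFGHIKLMNPQRSTVWY")
viral_lineage = parse_lineage("Viruses; dsDNA viruses, no RNA stage; Mimiviridae")

viral, cellular = [], []
for i in range(2):  # planted transfers: near-identical viral/cellular copies
    gene = "".join(rng.choice(aa, 60))
    copy = list(gene)
    for pos in rng.choice(60, size=2, replace=False):
        copy[pos] = rng.choice([a for a in aa if a != copy[pos]])
    viral.append(ReferenceProtein(f"viral_gene_{i}", gene, viral_lineage, "viral"))
    cellular.append(
        ReferenceProtein(
            f"oomycete_gene_{i}", "".join(copy),
            parse_lineage("Eukaryota; stramenopiles; Oomycetes; Phytophthora"),
            "cellular",
        )
    )
for i in range(10):  # decoys with no viral homology
    cellular.append(
        ReferenceProtein(
            f"decoy_{i}", "".join(rng.choice(aa, 60)),
            parse_lineage("Bacteria; Proteobacteria; Gammaproteobacteria; Vibrio"),
            "cellular",
        )
    )

candidates = screen_hgt(ReferenceDB(viral), ReferenceDB(cellular))
print(f"{len(candidates)} HGT candidate(s):")
for c in candidates:
    print(
        f"  {c.viral_peptide_id} <-> {c.cellular_protein_id} "
        f"(E1={c.e1:.1e}, E2={c.e2:.1e}; partner lineage: {c.cellular_lineage})"
    )
# Exactly the planted pairs surface; candidates are starting points for
# phylogenetic confirmation, not confirmed transfers.
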