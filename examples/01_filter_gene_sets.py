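"""Select metabolic gene sets from a collection by the name rule.

A gene set is kept when its name contains "metabol" but not "regul"
(case-insensitive), i.e. sets describing metabolic pathways themselves
rather than their regulation.
"""

import tempfile
from pathlib import Path

from metasub import filter_metabolic, parse_gmt

gmt = "\n".join([
    "KEGG_PYRUVATE_METABOLISM\tna\tPKM\tLDHA\tLDHB\tPDHA1",
    "GOBP_REGULATION_OF_LIPID_METABOLIC_PROCESS\tna\tPPARA\tSREBF1",
    "KEGG_CELL_CYCLE\tna\tCDK1\tCCNB1",
    "HALLMARK_XENOBIOTIC_METABOLISM\tna\tCYP1A1\tGSTM1\tNQO1",
]) + "\n"

path = Path(tempfile.mkdtemp()) / "sets.gmt"
path.write_text(gmt)

collection = parse_gmt(path)
kept = filter_metabolic(collection)

print(f"{len(collection)} sets in, {len(kept)} metabolic sets kept:")
for s in kept:
    print(f"  {s.name} ({len(s)} genes)")
# The regulation set and the non-metabolic set are dropped; the two
# pathway sets survive the substring rule.
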