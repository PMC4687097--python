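"""Rank Phase I predictions by CYP activity x abundance.

Score = sum over catalysing CYPs of (average activity x average abundance),
using the packaged, normalised 9-CYP liver statistics.  Enzymes without
liver data (e.g. 1A1, 1B1) are skipped and flagged.
"""

import csv
from importlib import resources

from proximal.ranking import rank

text = resources.files("proximal.data").joinpath("phase1_enzyme_sets.tsv").read_text()
rows = list(csv.DictReader(text.splitlines(), delimiter="\t"))

for compound in ("BPA", "PCB3"):
    items = [(r["metabolite"], r["enzymes"].split(";")) for r in rows if r["compound"] == compound]
    print(f"{compound}:")
    for s in rank(items):
        note = f" (no data: {','.join(s.enzymes_without_data)})" if s.enzymes_without_data else ""
        print(f"  rank {s.rank:2d}  score {s.reported_score:.4f}  {s.id}{note}")
    print()
# A higher score means more, and more abundant/active, CYPs can form the
# product; the top-ranked BPA product is the hydroxylated derivative.
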