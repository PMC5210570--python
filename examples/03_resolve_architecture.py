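"""Pick the maximum-score consistent domain architecture from overlapping hits.

Two compatible medium hits beat one strong hit that straddles them; a
discontiguous hit can interleave with a hit sitting in its gap.
"""

from cathkit import resolve_architecture
from cathkit.types import HitRecord, parse_region

hits = [
    HitRecord("proteinX", "famA", 6.0, parse_region("1-50")),
    HitRecord("proteinX", "famB", 6.0, parse_region("60-100")),
    HitRecord("proteinX", "famC", 9.0, parse_region("40-70")),
    HitRecord("proteinX", "famD", 10.0, parse_region("110-150,200-240")),
    HitRecord("proteinX", "famE", 6.0, parse_region("160-190")),
]

arch = resolve_architecture(hits)
print("chosen architecture:")
for hit in arch.chosen:
    print(f"  {hit.match_id:5s} score {hit.score:5.1f}  {hit.region.render()}")
print(f"total score {arch.total_score:g}")
print(
    "\nfamC overlaps both famA and famB, so the pair (12) beats it (9); the\n"
    "discontiguous famD leaves room for famE inside its gap.  No residue is\n"
    "claimed by two chosen hits."
)
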