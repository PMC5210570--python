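"""Column conservation (0-1) and the diversity-of-positions score (0-100).

Families with DOPs >= 70 are informative enough to be frozen: their
identifiers and membership stay stable across releases.
"""

from cathkit import column_conservation, dops_score, fixtures

targets = [1.0, 0.9, 0.75, 0.6, 0.45, 0.3]
msa = fixtures.make_msa_with_conservation(targets, depth=60, seed=1)
scores = column_conservation(msa)

print("column  target  conservation")
for j, (target, score) in enumerate(zip(targets, scores), start=1):
    print(f"{j:6d}  {target:6.2f}  {score:12.3f}")
dops = dops_score(scores)
print(f"\nDOPs = {dops:.1f}  ->  {'frozen' if dops >= 70 else 'updatable'} family")

flat = fixtures.make_msa_with_conservation([0.8] * 8, depth=50, seed=2)
print(f"uniform-conservation alignment: DOPs = {dops_score(column_conservation(flat)):.1f}")
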