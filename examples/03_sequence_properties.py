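"""GC content and homopolymer structure of encoded sequences.

M is chemically a methylated C, so G+C+M counts toward GC content and
M collapses onto C for homopolymer runs.  Random input gives every
letter ~1/5 stationary frequency, hence GC near 3/5 = 60%.
"""

from pentastore import profile_encoding
from pentastore.fixtures import random_file

for size in (5_929, 200_000):
    report = profile_encoding(random_file(size, seed=1), whole_stream=True)
    d = report.as_dict()
    print(f"{size:>7} bytes: {d['n_oligos']:>5} oligos, "
          f"GC mean {100*d['gc_mean']:.1f}% "
          f"(range {100*d['gc_min']:.0f}-{100*d['gc_max']:.0f}%), "
          f"max collapsed homopolymer {d['homopolymer_max']}")
# the GC band stays inside 50-70%; bigger files explore wider GC ranges
# and longer C-runs because more oligos sample the tails
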