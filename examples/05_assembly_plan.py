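"""Plan the staged ligation of 405 oligos into 15 groups (A to O).

Each oligo gets an 8-nt adaptor (108-nt units); groups of 27 split
into a 15-unit and a 12-unit subfragment.  The final unit carries no
trailing adaptor, so the subfragments assemble to 1,620 and 1,288 bp.
"""

from pentastore import encode_store, expected_fragment_lengths, plan_groups
from pentastore.adaptors import design_adaptors
from pentastore.fixtures import random_file

oligos, _ = encode_store(random_file(5929, seed=1))
plan = plan_groups(oligos, list(design_adaptors()), group_size=27)
labels = "".join(g.label for g in plan.groups)
len1, len2 = expected_fragment_lengths(plan)[0]
print(f"{len(oligos)} oligos -> {len(plan.groups)} groups ({labels})")
print(f"subfragment lengths per group: {len1} bp (15 units) and {len2} bp (12 units)")
# 15*108 = 1620; 12*108 - 8 = 1288 (terminal adaptor omitted)
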