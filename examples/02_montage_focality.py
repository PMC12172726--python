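"""Compare focality of the published bipolar montages against the HD ring.

Solves all five fixed montages on the same head and reports the anodal
focality index: the share of top-1% inward-current hotspot nodes that fall
inside the left dlPFC target.
"""

from tdcsphere import (
    build_atlas,
    build_head_model,
    focality_table,
    layout_1020,
    montage_library,
    solve_field,
)

head = build_head_model()
layout = layout_1020(head)
atlas, mesh = build_atlas(head, n_nodes=5000)

fields = [solve_field(head, m, mesh) for m in montage_library(layout)]
table = focality_table(fields, mesh)
anodal = table[table["polarity"] == "anodal"].set_index("montage")["index"]

print("anodal focality (top-1% hotspots inside left dlPFC, %):")
for mid, val in anodal.sort_values(ascending=False).items():
    print(f"  {mid:20s} {val:5.1f}")

# The HD ring keeps almost all of its hotspots in the target; the
# left-anode pad montages spread theirs across the frontal lobe; the
# dual-anode montage (anodes over both hemispheres) is least focal because
# half of its hotspots sit in the right hemisphere.
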