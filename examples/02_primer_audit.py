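"""Audit primers against the pseudoknot paired sites and position 1527.

A primer is unsafe for functional cloning when its footprint covers a
base-paired or lone variable position that is polymorphic in the
collection: its own base can then overwrite the template's and create a
non-native pair in the amplicon.
"""

from primer16s import (
    PairedSiteRegistry,
    SyntheticConfig,
    audit_primer,
    build_coordinate_map,
    composition_profile,
    generate_templates,
    load_packaged_primers,
    load_packaged_reference,
)

reference = load_packaged_reference()
primers = load_packaged_primers()
registry = PairedSiteRegistry()  # h2: 17-918, 18-917, 19-916; lone site 1527

cfg = SyntheticConfig(seed=7, flank_length=0)
records, _ = generate_templates(cfg, reference)
maps = {r.id: build_coordinate_map(r, reference) for r in records}

prof5 = composition_profile(records, maps, (1, 30))
prof3 = composition_profile(records, maps, (1520, 1542))

for name, prof in [("Bac8f(A)", prof5), ("Bac1f", prof5),
                   ("UN1541r(U)", prof3), ("UN1542r", prof3)]:
    v = audit_primer(primers[name], registry, prof)
    where = f" (position {', '.join(map(str, v.offending_positions))})" \
        if v.offending_positions else ""
    print(f"{name:11s} -> {v.verdict}{where}")
# The 8-27 and 1525-1541 footprints overlap polymorphic sites 19 and
# 1527; the 1-18 / 1528-1542 pair avoids both, which is why it is the
# safe choice for functional cloning.
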