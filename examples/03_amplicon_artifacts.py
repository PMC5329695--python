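"""Predict primer-templated base-pair artifacts in amplicons.

On a beta-like template (19C-916G), a forward primer carrying 19A
overwrites position 19 and fixes the non-native -- but functional --
A-G pair into the amplicon. The safe primer set leaves every pair
untouched.
"""

from primer16s import (
    SyntheticConfig,
    build_coordinate_map,
    generate_templates,
    load_packaged_primers,
    load_packaged_reference,
    predict_amplicon,
)

reference = load_packaged_reference()
primers = load_packaged_primers()

cfg = SyntheticConfig(seed=3, n_per_class={"gamma_like": 0, "beta_like": 5,
                                           "other": 0}, flank_length=0)
records, _ = generate_templates(cfg, reference)

for fwd_name in ("Bac8f(A)", "Bac1f"):
    print(f"forward primer {fwd_name}:")
    for r in records:
        cm = build_coordinate_map(r, reference)
        pred = predict_amplicon(r, primers[fwd_name], primers["UN1542r"], cm)
        subs = ", ".join(f"{s.ecoli_pos}:{s.template_base}>{s.imposed_base}"
                         for s in pred.substitutions) or "none"
        print(f"  {r.id}: substitutions [{subs}] risk={pred.risk_flag}")
    print()
# Bac8f(A) flags artifact_functional on every beta-like template
# (19 C>A, creating A-G); Bac1f imposes nothing at any paired site.
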