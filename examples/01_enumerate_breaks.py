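"""Enumerate the strand-break damage scheme over the h-telo sequence.

Canonical (CA) breaks leave ligatable 5'-PO4/3'-OH termini; non-canonical
(NC) breaks leave 5'-OH/3'-PO4 ends.  The standard scheme places 6 single
and 6 double breaks in the tetrad-connecting backbone (both chemistries)
and 3 CA-only breaks in the TTA loops: 2*(6+6)+3 = 27 configurations.
"""

import g4integrity as g4

configs = g4.enumerate_damage_scheme()
print(f"{len(configs)} damage configurations on {g4.HTELO_SEQUENCE}:\n")
for cfg in configs:
    sites = ",".join(cfg.site_classes)
    print(f"  {cfg.label:22s} [{sites:13s}] {g4.render_star_notation(cfg)}")

# every star marks a severed phosphodiester bond between the flanking
# residues; parsing the rendered notation reproduces the configuration
cfg = configs[0]
assert g4.parse_star_notation(g4.render_star_notation(cfg),
                              cfg.breaks[0].chemistry) == cfg
print("\nround-trip through star notation: OK")
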