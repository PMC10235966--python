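"""Scan 3'UTRs for miR-205 seed-match sites and render a duplex.

Plants one 8mer site in a random UTR screened free of chance matches, scans
with the canonical seed taxonomy (8mer > 7mer-m8 > 7mer-A1 > 6mer), and
prints the three-line pairing diagram.
"""

from follipulse import synth
from follipulse import targets as tg

utrs, truth, _ = synth.gen_utrs(
    synth.UtrSimParams(
        n_utrs=3,
        utr_length_range=(300, 300),
        planted_sites=((0, 120, "8mer"),),
        screen_chance=True,
        seed=5,
    )
)
mirna = tg.MicroRNA("miR-205", synth.MIR205_SEQUENCE)
for utr in utrs:
    for site in tg.find_seed_sites(mirna, utr):
        print(f"{site.gene}: {site.site_type} at {site.start}-{site.end} ({site.site_seq})")
        print(tg.render_duplex(mirna, utr, site))
print(
    "\nBars mark Watson-Crick pairs (colons would mark G:U wobbles in the\n"
    "flanks); the contiguous run under the miRNA 5' end is the seed match."
)
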