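"""Scan transcripts for miRNA target sites under the plant scoring rules.

Per duplex position: Watson-Crick 0, G:U wobble 0.5, mismatch 1.0, doubled
at miRNA positions 2-13 (the 5' core a plant miRNA must pair almost
perfectly).  A site needs <4 mismatches and penalty <= 4.
"""

from budmir.simlib import make_transcripts
from budmir.targets import hits_table, scan_targets

mirnas = {"miR-demo": "TGACAGAAGAGAGTGAGCACA"}
transcripts, planted = make_transcripts(7, mirnas, n_transcripts=20,
                                        sites_per_mirna=2, n_mismatch=2)

hits = scan_targets("miR-demo", mirnas["miR-demo"], transcripts)
print(hits_table(hits).to_string(index=False))

print("\nplanted site truth:")
print(planted.to_string(index=False))

h = hits[0]
print("\nbest site alignment (| Watson-Crick, o G:U, space mismatch),")
print("miRNA 5'->3' over the site read 3'->5':")
print(f"  miRNA 5'-{h.mirna_seq}-3'")
print(f"           {h.alignment}")
print(f"  site  3'-{h.site_seq[::-1]}-5'")
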