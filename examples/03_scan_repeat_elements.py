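"""Scan sequences for nuclear-receptor repeat elements (DR/ER/IR).

The grammar: two hexameric half-sites (AGGTCA / AGTTCA / AGAACA, with a
configurable mismatch budget) separated by 0-8 spacer bases, arranged as a
direct (DR), inverted (IR) or everted (ER) repeat.  The spacer count names
the element: DR1 has one spacer base.
"""

from nrpeak import HalfSiteModel, best_element, find_elements
from nrpeak.io_formats import revcomp

examples = {
    "DR1, A spacer":      "AGGTCA" + "A" + "AGGTCA",
    "IR1 (facing)":       "AGGTCA" + "T" + revcomp("AGGTCA"),
    "ER6 (everted)":      revcomp("AGTTCA") + "GATCGA" + "AGAACA",
    "1-mismatch DR4":     "AGGTCA" + "TTGC" + "AGcTCA".upper().replace("C", "C"),
}

model = HalfSiteModel()  # <=1 mismatch per half, <=2 total
for name, seq in examples.items():
    calls = find_elements(seq, model)
    best = best_element(calls)
    print(f"{name:18s} {seq:22s} -> {best.label:5s} "
          f"(mismatches={best.mismatches}, strand={best.strand})")
# 'label' is family+spacer; ties break DR < IR < ER, then smaller spacer.

# an exact-match scan (budget 0) keeps only perfect elements
strict = HalfSiteModel(max_mismatch_per_half=0, max_total_mismatch=0)
noisy = "AGGTCA" + "G" + "AGTTCA"
print(f"\nexact-mode scan of DR1 example: "
      f"{[c.label for c in find_elements(noisy, strict)]}")
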