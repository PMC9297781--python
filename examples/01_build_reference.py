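"""Build a fragment-length score table from tumour vs non-malignant cfDNA.

Tumour-derived cfDNA fragments run shorter than fragments of white-blood-cell
origin. The score table captures this as a per-length log2 density ratio:
positive where a length is enriched in tumour cfDNA, negative where it is
enriched in non-malignant cfDNA.
"""

import fragmrd as fm

# a tumour-tagged reference of ~21.7k mutation-carrying fragments, and a
# large non-malignant pool, both from the generator's default length mixtures
tumour = fm.sample_fragment_pool(
    fm.TUMOUR_PROFILE, 21_705, seed=1, sample_id="tumour", source_label="tumour_reference"
)
nonmalignant = fm.sample_fragment_pool(fm.NONTUMOUR_PROFILE, 5_000_000, seed=2, sample_id="nm")

table = fm.build_score_table(tumour, nonmalignant, n_boot=1000, n_sample=10_000, seed=3)

print(f"score range: [{table.scores.min():+.2f}, {table.scores.max():+.2f}] (capped at +/-5)")
for lo, hi in ((130, 150), (150, 160), (180, 210), (250, 300)):
    print(f"mean score {lo}-{hi} bp: {table.scores[lo:hi + 1].mean():+.2f}")
print(
    "\nShort (130-150 bp) and disomal-shoulder (250-300 bp) fragments carry positive\n"
    "weight (tumour-like); the 180-210 bp band is non-malignant-like; the abundant\n"
    "150-160 bp core is nearly neutral, as both sources are rich there."
)
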