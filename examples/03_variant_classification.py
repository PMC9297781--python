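"""Variant-level fragmentation score (VFS): tumour- vs blood-derived variants.

The per-fragment score averaged over the reads supporting one variant
separates tumour-derived variants (short supporting fragments) from
CHIP-like blood variants, without needing the blood-cell pellet. Variants
with fewer than eight supporting reads are left indeterminate.
"""

import fragmrd as fm

cohort = fm.sample_cohort(fm.SyntheticCohortConfig(seed=11))
tumour = fm.merge_pools(
    [p.tumour_fragments for p in cohort.patients], "tumour", "tumour_reference"
)
nonmalignant = fm.pooled_controls(cohort.controls)
table = fm.build_score_table(tumour, nonmalignant, n_boot=1000, seed=1)
thresholds = fm.VfsThresholds(nonmalignant, table, seed=2)

truth = cohort.variant_truth.set_index(["patient_id", "chrom", "pos", "ref", "alt"])["origin"]
labels, truths = [], []
for p in cohort.patients:
    grouped = {}
    for s in p.support:
        if s.compartment in ("preop_plasma", "postop_plasma"):
            grouped.setdefault(s.key, []).append(s)
    for key, recs in grouped.items():
        origin = truth.get((p.patient_id, *key))
        if origin not in ("tumour", "blood"):
            continue
        vfs = fm.classify_variant(fm.variant_fs(recs, table), thresholds, min_reads=8)
        labels.append(vfs.classification)
        truths.append(origin)

tp = sum(l == t == "tumour" for l, t in zip(labels, truths))
fn = sum(l != "tumour" and l != "indeterminate" and t == "tumour" for l, t in zip(labels, truths))
tn = sum(l == t == "blood" for l, t in zip(labels, truths))
fp = sum(l == "tumour" and t == "blood" for l, t in zip(labels, truths))
ind = labels.count("indeterminate")
print(f"variants classified: {len(labels)} ({ind} indeterminate below 8 reads)")
print(f"sensitivity (tumour): {tp / (tp + fn):.1%}   specificity (blood): {tn / (tn + fp):.1%}")
print(f"performance score (+1 right / -1 wrong / 0 indeterminate): "
      f"{fm.vfs_performance_score(labels, truths)}")
print(
    "\nSupporting-fragment lengths alone recover the tumour/blood origin of\n"
    "nearly all variants with at least eight supporting reads."
)
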