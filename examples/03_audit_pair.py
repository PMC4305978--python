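"""Audit an expert-corrected (cD) mark set against the machine's dD.

Generates a spot with injected detection and labeling errors, decodes
the dD, simulates a perfect expert's cD, audits the pair on a full
counting-frame tiling, and compares the audit tallies with the
generator's event log — they agree exactly.
"""

from ihcaudit import (
    Category, ErrorModel, audit_spot, event_tallies, full_tiling_grid,
    generate_spot, marks_from_markup, simulate_cd,
)

em = ErrorModel(p_miss_tissue=0.03, p_miss_nuclear=0.2,
                false_detections_per_spot=30.0,
                p_label_flip_pos=0.01, p_label_flip_neg=0.02, seed=5)
spot = generate_spot(500, 30.0, 896, em, "audit-demo")
dd = marks_from_markup(spot.markup_mask, spot_id="audit-demo")
cd = simulate_cd(spot, dd)
grid = full_tiling_grid(896, 896, 150, 150)

audit = audit_spot(dd, cd, grid, spot.tissue_mask)
expected = event_tallies(spot.event_log, grid)

print(f"dD marks {len(dd)}, cD marks {len(cd)}, edits {audit.n_edits}")
print(f"Ki67% dD {audit.ki67_dd:.1f} vs cD {audit.ki67_cd:.1f}")
print(f"{'category':28s} {'audit':>6s} {'injected':>9s}")
for cat in Category:
    if cat.value.startswith("TRUE"):
        continue
    print(f"{cat.value:28s} {audit.tallies[cat]:6d} {expected[cat]:9d}")
# Every edit the audit attributes (missed by the tissue mask vs by the
# nuclear segmenter, spurious detections, label flips) matches the
# injected event log, category for category.
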