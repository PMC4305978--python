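"""Series statistics over a cohort of audited spots.

Generates a small spot series under the default error regime, audits
every spot, and summarizes agreement (regression, Bland-Altman) and
expert editing effort.
"""

from ihcaudit import (
    audit_spot, bland_altman, generate_grid, generate_series,
    linear_regression, marks_from_markup, simulate_cd, summarize_effort,
)

spots = generate_series(n_spots=12, n_nuclei=660, image_size=1024, seed=42)
audits = []
for i, spot in enumerate(spots):
    dd = marks_from_markup(spot.markup_mask, spot_id=spot.spot_id)
    cd = simulate_cd(spot, dd)
    grid = generate_grid(1024, 1024, 150, 150, 300, 300, seed=i)
    audits.append(audit_spot(dd, cd, grid, spot.tissue_mask))

summary = summarize_effort(audits)
x = [a.ki67_dd for a in audits]
y = [a.ki67_cd for a in audits]
reg = linear_regression(x, y)
ba = bland_altman(x, y)

print(f"{summary.n_spots} spots, {summary.total_cd_nuclei} reviewed cD nuclei")
print(f"edits: {summary.total_edits} ({summary.pct_edits:.1f}% of nuclei), "
      f"savings fraction {summary.savings_fraction:.3f}")
print(f"Ki67% regression cD~dD: slope {reg.slope:.3f}, "
      f"intercept {reg.intercept:.2f}, R^2 {reg.r_squared:.3f}")
print(f"Bland-Altman: bias {ba.bias:.2f} pp, "
      f"limits of agreement [{ba.loa_low:.2f}, {ba.loa_high:.2f}]")
# The savings fraction is the share of reviewed marks the expert did
# not have to place or fix by hand; R^2 near 1 with small bias says the
# per-spot Ki67% survives the machine's cell-level errors largely intact.
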