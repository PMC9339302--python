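"""Score chromosome condensation in synthetic DAPI fields.

Renders fields of DAPI-like nuclear masses for two conditions —
wildtype-like (compaction near 1.0) and hypercondensed (compaction
around 0.8) — with per-field variability in compaction, emulating the
cell-to-cell heterogeneity of a real culture. Each DNA mass is scored
against the 62-px circular ROI template, and per-field matched
percentages are compared with a two-tailed t-test.
"""

import numpy as np

from poolseg import (
    ImageFieldSpec,
    MaskSpec,
    render_field,
    score_fields,
    t_two_sample,
)

mask = MaskSpec()  # 62 px circle, fill >= 0.90 or edge contact >= 0.75
rng = np.random.default_rng(8)


def percentages(theta_low: float, theta_high: float, n_fields: int) -> list:
    out = []
    for i in range(n_fields):
        theta = float(rng.uniform(theta_low, theta_high))
        spec = ImageFieldSpec(n_nuclei=6, compaction=theta,
                              loop_probability=0.5, noise_sd=0.01,
                              seed=int(rng.integers(2**31)))
        field = render_field(spec, field_id=f"f{i}")
        out.append(score_fields([field], mask).percent_matched_total)
    return out


wildtype = percentages(0.92, 1.0, 10)
condensed = percentages(0.70, 0.95, 10)
print(f"wildtype-like fields:    {[round(v) for v in wildtype]}")
print(f"hypercondensed fields:   {[round(v) for v in condensed]}")
print(f"means: wildtype {np.mean(wildtype):.1f}% vs "
      f"hypercondensed {np.mean(condensed):.1f}% matched")

result = t_two_sample(wildtype, condensed)
print(f"two-tailed t-test: t={result.statistic:.2f}, df={result.df:.0f}, "
      f"p={result.p_value:.4g}")
# Masses below ~0.94 compaction cover too little of the template and sit
# too far inside its boundary to match; the t-test on per-field matched
# percentages quantifies the separation between the two conditions.
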