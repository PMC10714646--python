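"""Downstream statistics: alt-allele preference, chromatin-state
enrichment with meta-analysis, PWM allele scoring and the TF screen.

All inputs here are tiny toys; with real data the annotation BED would
be a ChromHMM 15-state segmentation, the motifs a JASPAR/MEME library,
and the foreground the disease-associated AShM sites.
"""

import numpy as np
import pandas as pd

from ashmtwin.enrichment import (
    alt_preference_odds_ratio,
    direction_consistency_test,
    fisher_enrichment,
    meta_enrichment,
    tf_correlation_screen,
)
from ashmtwin.pwm import PWM, pwm_allele_scores

# 1. the affected-vs-unaffected alternative-allele preference contrast:
# over 807 sites, 88% alt-hyper in affected vs 60% in unaffected cotwins
r = alt_preference_odds_ratio(807, 0.88, 0.60)
print(f"alt-preference 2x2 table: {r.a}/{r.b} vs {r.c}/{r.d}")
print(f"odds ratio {r.odds_ratio:.2f} (95% CI {r.ci_low:.2f}-{r.ci_high:.2f}), "
      f"Fisher p = {r.p_value:.1e}")

# 2. chromatin-state enrichment of a site set, meta-analyzed over tissues
ann = pd.DataFrame({"chrom": "chr1", "start": [0, 4000], "end": [2000, 8000],
                    "label": ["Enh", "Quies"]})
fg = pd.DataFrame({"chrom": "chr1", "pos": [100, 500, 1500, 5000]})
bg = pd.DataFrame({"chrom": "chr1", "pos": [100, 500, 1500, 5000] + list(range(130, 9000, 300))})
per_tissue = [fisher_enrichment(fg, bg, ann) for _ in range(3)]
enh = pd.concat([t[t["label"] == "Enh"] for t in per_tissue])
meta = meta_enrichment(enh)
print(f"\nEnh enrichment, 3-tissue fixed-effect meta: OR {meta['odds_ratio']:.2f} "
      f"(SE of log OR {meta['se']:.2f}, p = {meta['p_value']:.3f})")

# 3. direction consistency of a histone mark with hydroxymethylation
print(f"\nbinomial direction-consistency p (14 same of 16): "
      f"{direction_consistency_test(14, 16):.4f}")

# 4. allele-specific motif scoring, min-max scaled to the motif's range
pwm = PWM("TOY_TF", np.array([[0.7, 0.1, 0.1, 0.1],
                              [0.1, 0.1, 0.7, 0.1],
                              [0.1, 0.1, 0.1, 0.7]]))
score = pwm_allele_scores(pwm, "CCAGTCC", 2, ref="A", alt="C", site_id="rs_toy")
print(f"\nmotif {score.tf_id}: scoreRef {score.score_ref:.3f}, "
      f"scoreAlt {score.score_alt:.3f}, effect {score.effect:.3f}")

# 5. correlation screen: does a TF's allele effect track alt 5hmC levels?
rng = np.random.default_rng(0)
alt_level = rng.uniform(0.5, 0.95, 8)
effect = 0.1 + 0.6 * (alt_level - 0.5) + rng.normal(0, 0.03, 8)
res = tf_correlation_screen(effect, alt_level)
print(f"TF screen: r = {res['r']:.2f}, p = {res['p_value']:.4f}, "
      f"significant = {res['significant']} ({res['sign']})")
# |r| > 0.5 with p < 0.05 flags the TF; a positive sign means larger
# binding disruption at sites where the alternative allele carries more 5hmC.
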