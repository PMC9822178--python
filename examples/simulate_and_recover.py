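"""Generate a synthetic two-period corpus and recover its parameters.

The default profile draws ~30k records with per-period sentiment
prevalences and an after-midnight negative-odds multiplier of 1.43. The
temporal analysis should recover that multiplier (within-period contrasts)
and the share table should recover the prevalences.
"""

from sentifuse import (
    default_study_profile,
    sentiment_share_table,
    simulate_frame,
    temporal_negative_analysis,
)

cfg = default_study_profile(seed=1)
frame = simulate_frame(cfg)
print(f"simulated {len(frame)} records "
      f"({cfg.n_pre} prepandemic + {cfg.n_peri} peripandemic)")

table = sentiment_share_table(frame)
print()
print(table[["n_pre", "pct_pre", "n_peri", "pct_peri", "odds_ratio"]].round(3))

report = temporal_negative_analysis(frame)
print()
for name in ("after_vs_before", "after_vs_before_pre", "after_vs_before_peri"):
    r = report.contrasts[name]
    print(f"{name:>22}: OR {r.or_point:.3f} ({r.ci_low:.3f}-{r.ci_high:.3f})")
print()
print("The within-period after-vs-before-midnight ORs bracket the generating")
print(f"multiplier {cfg.after_midnight_negative_odds_multiplier}; the share table "
      "reproduces the configured prevalences")
print("(55% peri negative, 46.7% pre negative) up to sampling noise.")
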