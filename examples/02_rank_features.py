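"""Rank every m/z point by its two-sample t statistic.

Each grid point is treated as one feature; the statistic compares the
cancer and control intensity distributions with unbiased group variances
and pooled degrees of freedom n_d + n_c - 2.  The top ranks should land
on the planted markers.
"""

from seldiclass import default_paper_like_config, generate, rank_features

cohort, truth = generate(default_paper_like_config(seed=1))
ranking = rank_features(cohort)

print(f"degrees of freedom: {ranking.df}")
print("top 8 features by |t|:")
print(ranking.to_frame().head(8).to_string(index=False))
print("planted marker indices:", truth.mz_index.tolist())
# |t| around 20 at the markers vs ~2-3 elsewhere: the planted 1.5-unit
# amplitude gap stands far above the multiple-comparison noise floor.
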