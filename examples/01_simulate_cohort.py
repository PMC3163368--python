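"""Simulate a SELDI-like case/control serum cohort with planted markers.

The default configuration mirrors the structure of the public
high-resolution ovarian-cancer WCX2 dataset: 12,000 m/z points over
700-12,000 Da, 95 controls and 121 cancers, and four low-amplitude
discriminatory peaks (near 8150 Da and inside 8450-8740 Da) whose
disease-control amplitude gap is three noise standard deviations.
"""

from seldiclass import default_paper_like_config, generate

config = default_paper_like_config(seed=1)
cohort, truth = generate(config)

print(f"samples per class: {cohort.class_counts()}")
print(f"grid: {cohort.n_features} m/z points, "
      f"{cohort.grid.values[0]:.0f}-{cohort.grid.values[-1]:.0f} Da")
print("planted markers (grid index, m/z, amplitude gap):")
print(truth.to_string(index=False))
# Each 'delta' is the intensity difference a cancer spectrum carries at that
# m/z on average; at 3x the noise SD it is invisible to the eye but easily
# detected by the t statistic across ~100 samples per group.
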