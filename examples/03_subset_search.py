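"""Search for a 5-feature discriminatory m/z subset.

Candidate k-subsets are rated by leave-one-out nearest-centroid accuracy
in the k-dimensional amplitude space; the elitist search reshuffles the
indices of the highest-rated subsets (with mutation) until some subset
fully discriminates the cohort (rating 1.0) or the budget runs out.  A
reduced 200-point grid keeps the run short.
"""

from seldiclass import SearchConfig, generate, search_subsets
from seldiclass.simulate import PeakSpec, SimConfig, shared_peak

config = SimConfig(
    grid_min=700.0, grid_max=2700.0, n_points=200,
    n_control=40, n_disease=40,
    baseline_scale=10.0, baseline_decay=5e-4,
    shared_peaks=(shared_peak(1200.0, 15.0, 100.0),),
    marker_peaks=tuple(
        PeakSpec(c, 10.0, 0.5, 2.0) for c in (1700.0, 1900.0, 2100.0, 2300.0, 2500.0)
    ),
    noise_sd=0.5, seed=4,
)
cohort, truth = generate(config)

best, log = search_subsets(cohort, SearchConfig(k=5, seed=0))
print(f"best subset indices: {best.indices}")
print(f"m/z values: {[round(float(cohort.grid.values[i]), 1) for i in best.indices]}")
print(f"rating: {best.rating:.3f} after {len(log)} iterations")
print(f"best-rating log: {[round(r, 3) for r in log]}")
print(f"planted markers at indices {truth.mz_index.tolist()}")
# rating 1.0 means every held-out sample is closer to its own class
# centroid than to the other class's: the subset fully separates the cohort.
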