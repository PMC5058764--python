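"""Quantify DAB staining by optical densitometry.

Synthesizes H-DAB stained image patches for a 'low-grade' group (strong PSA
staining) and a 'high-grade' group (weak staining), deconvolves the DAB
channel, samples triplicate random regions, and compares mean optical
densities with a two-sided t-test.
"""

import numpy as np

from tpsad import group_compare, hdab_deconvolve, sample_region_ods, simulate_ihc_rgb

groups = {"low_grade": 0.8, "high_grade": 0.4}  # planted DAB optical densities
ods, labels = [], []
for group, target in groups.items():
    for i in range(8):
        rgb = simulate_ihc_rgb(dab_od=target, hema_od=0.25, seed=100 * (group == "low_grade") + i)
        dab_channel = hdab_deconvolve(rgb)["dab"]
        region_ods, mean_od, _ = sample_region_ods(dab_channel, region_size=64, seed=i)
        ods.append(mean_od)
        labels.append(group)
    group_mean = np.mean([o for o, g in zip(ods, labels) if g == group])
    print(f"{group:11s}: planted OD {target:.2f}, measured mean OD {group_mean:.3f}")

stat, p = group_compare(ods, labels, test="ttest")
print(f"\ntwo-sided t-test, low vs high grade: t = {stat:.2f}, p = {p:.2e}")
# The measured densities recover the planted stain amounts; the t-test
# separates the groups, the same readout used to show lower PSA protein
# expression in high-grade tumours.
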