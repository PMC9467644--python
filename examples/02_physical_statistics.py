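"""Per-cell physical statistics of a simulated mitochondrial population.

Speed is distance moved per frame per trajectory; inter-mitochondrial
distance is the frame-averaged nearest-neighbour spacing; co-localization
time counts frames a pair spends within the 1.6 µm encounter threshold.
"""

from mitosocial import SimulationConfig, physical_summary, simulate_cell

sim = simulate_cell(SimulationConfig(seed=42))
ps = physical_summary(sim.cell.mito)

print(f"tracks analysed:            {ps.n_tracks}")
print(f"mean speed:                 {ps.mean_speed_um_per_frame:.3f} um/frame")
print(f"median speed:               {ps.median_speed_um_per_frame:.3f} um/frame")
print(f"mean inter-mito distance:   {ps.mean_intermito_distance_um:.3f} um")
print(f"mean coloc time (met pairs):{ps.mean_coloc_time_frames:.2f} frames")
print(f"mean coloc time (all pairs):{ps.mean_coloc_time_all_pairs:.3f} frames")
# Spacing ~2 um and co-localization episodes of several-to-tens of frames
# are the scales typical of wild-type hypocotyl cells; the positive-pair
# mean is the headline statistic, the all-pairs mean is reported alongside.
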