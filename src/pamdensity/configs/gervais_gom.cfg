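# Gervais' beaked whale detection scenario, Gulf of Mexico defaults
[scenario]
source_level_mean = 220
source_level_sd = 3
peak_frequency = 43.8
absorption = 11.30
directivity_index_range = 24, 28
detection_threshold = 121
receiver_altitude = 10
animal_altitude_range = 175, 225
monitoring_radius_w = 4
pitch_sd_range = 5, 15
beam_loss_floor = 40

[behavior]
azimuth_sweep_range = 140, 160
elevation_sweep_foraging_range = 55, 65
elevation_sweep_descent_range = 10, 15
descent_fraction = 0

[sim]
iterations = 500
animals_per_iteration = 10000
range_bin = 100
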