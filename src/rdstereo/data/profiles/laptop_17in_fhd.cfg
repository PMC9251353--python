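# Secondary profile: 17.3-in 16:9 full-HD 3D notebook panel
diagonal_mm = 439.4
aspect_ratio = 16:9
resolution_px = 1920x1080
viewing_distance_mm = 5000
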