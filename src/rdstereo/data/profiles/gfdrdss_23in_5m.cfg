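# Reference profile: 23-in 4K autostereoscopic panel viewed at 5 m
diagonal_mm = 584.2
aspect_ratio = 16:9
resolution_px = 3840x2160
viewing_distance_mm = 5000
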