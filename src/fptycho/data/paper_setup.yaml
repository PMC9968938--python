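# Default instrument profile: 32x32 LED matrix, red channel, 0.1-NA objective.
led_rows: 32
led_cols: 32
led_pitch_mm: 4.0
led_distance_mm: 46.7
wavelength_um: 0.632
na_objective: 0.1
magnification: 4.29
camera_pixel_um: 4.54
frame_rows: 1460
frame_cols: 1940
bit_depth: 12
n_leds_active: 177
axis_offset_mm: [0.0, 0.0]
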