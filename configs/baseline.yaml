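m1: 0.000125
m2: 2.5e-05
k1: 150.0
k2: 15.0
kc: 85.0
r1: 0.04
r2: 0.008
contact_stiffness_ratio: 3.0
fold_length: 0.014
d1: 0.0025
d2: 0.0005
rest_area1: 3.0e-06
rest_area2: 2.0e-06
driving_pressure: 800.0
min_gap: 0.0002
air_density: 1.2
cd_glottis: 1.0
cd_stenosis: 1.0
subglottal_area: 0.00025
tract_length: 0.174
sound_speed: 351.88
dt: 1.0e-05
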