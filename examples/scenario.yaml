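# Reference step-warming scenario on the synthetic world.
co2_schedule:
  t_pre: 50.0          # kyr at the pre-event CO2 level
  co2_pre: 680.0       # ppm
  co2_peak: 1590.0
  body_duration: 70.0  # kyr at the peak after the onset step
  t_recovery1: 150.0   # kyr after onset
  co2_recovery1: 780.0
  t_end: 200.0
  co2_end: 680.0
  step_kyr: 10.0
alpha: 0.01            # evolutionary adaptation rate per step
dispersal_scale: 1100.0  # km per 10 kyr (Weibull scale, shape 1.75)
k_nichebreadth: 0.03   # climatic niche penalty (0 / 0.03 / 0.10)
co2_fertilisation: true
n_lat: 18
n_lon: 36
warming_offset: 8.0    # degC land-mean warming of the peak endmember
world_seed: 42
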