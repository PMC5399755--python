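# Osmotic-upshift-like cohort member: turning rate ramps from 10/min to
# a 30/min plateau at 240 s, mirroring the gradual aversive response.
simulation:
  duration_s: 300.0
  turn_rate: {ramp: [10, 30]}
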