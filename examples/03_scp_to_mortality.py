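"""From supercooling points to winter survival.

Generates the calibrated synthetic SCP sample (a freeze-avoidant snail
dies when ambient temperature reaches its SCP), then shows the freeze
mortality implied by a range of snowless-winter minima and the winter
survival parameter each would leave.
"""

from vertigopop import adjust_winter_survival, mortality_from_scp, scp_sample

sample = scp_sample(seed=1, n=200)
s = sample.summary()
print(f"synthetic SCP sample: n={s['n']}, mean={s['mean']:.1f} degC, "
      f"median={s['median']:.1f}, range [{s['min']:.1f}, {s['max']:.1f}]")

print("\nt_min (degC)   freeze mortality   adjusted d_w (base 0.7)")
for t_min in (-6.3, -8.0, -10.0, -12.0, -14.0, -15.0):
    m = mortality_from_scp(sample, t_min)
    d_w = adjust_winter_survival(0.7, m)
    print(f"{t_min:10.1f} {m:16.2%} {d_w:18.3f}")

print("\nThe mortality column is the fraction of individuals whose SCP lies "
      "at or above t_min; it multiplies into the baseline winter survival.")
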