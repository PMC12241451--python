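"""Snow-cover-disappearance experiment: the five canonical scenarios.

Without insulating snow, the winter minimum air temperature acts directly
on the snails; each scenario imposes the published freeze-mortality
fraction for its minimum (-5.5, -8, -10, -14 degC), multiplied into the
baseline winter survival of 0.7.  Prints a comparison table: final-season
statistics, quasi-extinction time (first month the total stays below one
individual) and the growth statistic lambda.
"""

from vertigopop import (
    build_paper_scenarios,
    default_initial_state,
    default_parameters,
    run_scenario,
)

params = default_parameters()
start = default_initial_state()

print("scen  t_min  mortality   d_w    mean_final  extinct_at  lambda")
for spec in build_paper_scenarios():
    summary, _ = run_scenario(spec, params, start, n_seasons=20)
    t_min = f"{spec.t_min:g}" if spec.t_min is not None else "-"
    ext = summary.time_to_extinction or "-"
    lam = f"{summary.lambda_pct:.1f}%" if summary.lambda_pct is not None else "-"
    print(f"{spec.name:>4} {t_min:>6} {spec.mortality:9.2f} "
          f"{summary.d_w:6.3f} {summary.mean_final:12.1f} {str(ext):>10} {lam:>9}")

print("\nColder snowless winters only hurt: mean final size and persistence "
      "fall monotonically from scenario 0 to 4; the harshest scenarios end "
      "in quasi-extinction (total < 1 individual).")
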