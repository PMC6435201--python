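"""What the Na+/K+ pump buys, and what it costs.

Switch on a hypothetical electroneutral 3Na:3K pump in a cation-only cell
(gNa = gK = 1e10 ions/(s*V), Cl- impermeant) and watch Na+ and K+ swap
over a few seconds.  Then find, by bisection on the pump rate, the point
where the steady state has [Na]i = [K]i = 75 mM -- which is exactly where
the steady membrane potential is most negative.
"""

from chargediff import (
    SimSettings,
    find_rate_for_condition,
    get_scenario,
    run_scenario,
)
from chargediff.io import eng

scenario = get_scenario("pump_neutral_transient")  # rate 2.4e10 at t = 0
traj = run_scenario(scenario)
f = traj.final_state

print("Electroneutral 3Na:3K pump, rate 2.4e10 cycles/s, switched on at t=0:")
print(f"  activity at start (Na_i = 145 mM): {eng(traj.Ap[1])}/s")
print(f"  Em dips to {traj.Em.min() * 1e3:.2f} mV, then recovers")
print(f"  after {f.t:.0f} s: Na_i = {f.Na_i:.2f} mM, K_i = {f.K_i:.2f} mM, "
      f"Em = {f.Em * 1e3:+.2f} mV")
print(f"  steady ATP consumption: {eng(traj.Ap[-1])}/s")
print()

base = get_scenario("pump_sweep", x=3, y=3)
rate, rep = find_rate_for_condition(
    base, lambda r: r.state.Na_i - r.state.K_i, (5e7, 1e9),
    settings=SimSettings(st=1e-3, max_steady_time=3600.0), rtol=1e-9,
)
print("Tuning the same pump so that steady-state Na_i = K_i:")
print(f"  rate {eng(rate)}/s -> activity {eng(rep.atp_per_sec)} ATP/s")
print(f"  Na_i = K_i = {rep.state.Na_i:.2f} mM, Em = {rep.state.Em * 1e3:.2f} mV")
print()
print("This is the bottom of the U-shaped Em-vs-activity curve: pumping")
print("harder than this ('overpumping') makes Em *less* negative while")
print("spending more ATP.")
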