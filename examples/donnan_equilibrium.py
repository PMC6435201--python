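"""Donnan equilibrium from first principles.

A cell with 135 mM of impermeant monovalent anion, symmetric Na+ (150 mM)
and a tenfold inward Cl- gradient becomes permeable to Na+ and Cl- at
t = 0.  With a water-tight membrane the system relaxes into a true Donnan
equilibrium: both ions end up at their Nernst potentials and the product
rule [Na]i[Cl]i = [Na]o[Cl]o holds.
"""

from chargediff import donnan_residual, get_scenario, run_scenario

scenario = get_scenario("donnan_novol")
traj = run_scenario(scenario, t_end=1200.0)  # 20 simulated minutes
final = traj.final_state

print("After 20 min with gNa = gCl = 1e10 ions/(s*V), no water flux:")
print(f"  [Na+]i = {final.Na_i:8.3f} mM   (started at 150)")
print(f"  [Cl-]i = {final.Cl_i:8.3f} mM   (started at 15)")
print(f"  Em     = {final.Em * 1e3:8.3f} mV   (started at 0)")
print(f"  volume = {final.vol / scenario.cell.vol * 100:.1f} %  (unchanged: no water)")
resid = donnan_residual(final, traj.final_bath)
print(f"  Donnan product residual [Na]i[Cl]i/([Na]o[Cl]o) - 1 = {resid:.2e}")
print()
print("Both permeant ions sit at the membrane potential (-11.6 mV), so no")
print("energy is spent holding this state; the residual shrinks toward 0")
print("as the run is extended (to ~1e-10 by 90 min).")
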