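"""Chloride conductance is what couples voltage to volume.

Open a Cl- conductance on a pump-leak resting state (Em = -43.3 mV, set
entirely by the cations).  Whatever Cl_i starts at, it is forced to the
single value whose Nernst potential equals that Em; the Na+ and K+
concentrations barely move, and the *volume* absorbs the difference.
"""

from chargediff import SimSettings, get_scenario, nernst_potential, steady_state

for cl_start in (15.0, 45.0):
    sc = get_scenario("gcl_opening", Cl_i=cl_start)
    rep = steady_state(sc, SimSettings(st=2.5e-4, max_steady_time=3600.0))
    s = rep.state
    e_cl = -nernst_potential(rep.bath.Cl_o, s.Cl_i, 1, sc.params.T)
    print(f"start Cl_i = {cl_start:4.0f} mM -> resting Cl_i = {s.Cl_i:.2f} mM, "
          f"Em = {s.Em * 1e3:.2f} mV, E_Cl = {e_cl * 1e3:.2f} mV, "
          f"volume = {s.vol / sc.cell.vol * 100:6.2f} %")

print()
print("Both starting points land on the same Cl_i (~29.6 mM) where")
print("E_Cl = Em; the cell that had to *gain* NaCl+KCl swelled, the one")
print("that had to lose it shrank. Cations and ATP cost are unchanged --")
print("volume is chloride's business.")
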