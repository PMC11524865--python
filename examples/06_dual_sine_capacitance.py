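"""Membrane capacitance from raw currents with the dual-sine technique.

Simulates the steady-state current of the 3-element patch circuit (series
resistance into membrane resistance parallel membrane capacitance) under the
two-sine command (10 mV at 390.6 and 781.2 Hz riding on a DC step), then
solves (Rs, Rm, Cm) from the FFT admittances at exactly the two stimulus
frequencies.  Repeating this at every 4 mV staircase step reconstructs the
full capacitance-voltage curve.
"""

import numpy as np

from orthoexpress import (
    NLCParams, PatchCircuit, SimConfig, nlc_curve, simulate_two_sine_current,
    two_sine_capacitance,
)

n = 2560  # ten periods of 390.625 Hz at 100 kHz sampling

circuit = PatchCircuit(rs_mohm=10.0, rm_mohm=500.0, cm_pf=10.0)
v, i = simulate_two_sine_current(circuit, n)
est = two_sine_capacitance(i, v)
print(f"single step: Cm = {est.cm_pf:.3f} pF, Rs = {est.rs_mohm:.2f} MOhm, "
      f"Rm = {est.rm_mohm:.1f} MOhm  (truth 10 pF / 10 MOhm / 500 MOhm)")

truth = SimConfig(seed=6).nlc_truth
print("\nvoltage (mV)   true Cm (pF)   estimated Cm (pF)")
for v_step in np.arange(-120.0, 61.0, 24.0):
    cm_true = float(nlc_curve(v_step, truth))
    v_tr, i_tr = simulate_two_sine_current(
        PatchCircuit(10.0, 500.0, cm_true), n, v_dc_mv=float(v_step))
    est = two_sine_capacitance(i_tr, v_tr)
    print(f"{v_step:12.0f} {cm_true:14.3f} {est.cm_pf:19.3f}")
# The estimated column tracks the bell-shaped NLC curve: capacitance peaks
# near V1/2 = -54 mV and relaxes to the linear capacitance at the extremes.
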