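"""Relax one stem cell to steady state under different Dkk1 environments.

Integrates the intracellular system of a single cell with frozen inputs
and prints the quasi-steady levels.  Rising extracellular Dkk1 suppresses
LEF/TCF and the proliferation factor and, through the Notch/HES chain,
lets the differentiation factor climb — the single-cell kernel of the
anti-proliferative, pro-maturation Dkk1 effect.
"""

from quorumfate import CellInputs, CellState, default_params, integrate_step

params = default_params()

print(f"{'Dkk1 (ng/mL)':>12} {'LEF/TCF':>8} {'PF':>7} {'Notch':>7} {'HES':>7} {'DF':>7}")
for dkk in (0.0, 5.0, 13.0, 25.0):
    inputs = CellInputs(wnt_ext=params.wnt_ext, dkk_ext=dkk,
                        bound_ecad=4.0, dsl_sum=4 * params.dsl_level)
    cell = CellState(lef_tcf=1.0, notch=5.0, hes=4.0)
    for _ in range(6000):                       # 600 h, ample relaxation
        cell = integrate_step(cell, inputs, params, 0.1)
    print(f"{dkk:12.1f} {cell.lef_tcf:8.3f} {cell.pf:7.3f} "
          f"{cell.notch:7.3f} {cell.hes:7.3f} {cell.df:7.3f}")

print(f"\nDivision requires PF >= {params.pf_threshold}; "
      f"differentiation fires at DF >= {params.df_threshold}.")
print("High Dkk1 pushes a supported cell from the proliferative regime "
      "(high PF, low DF) into the differentiation-committed one.")
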