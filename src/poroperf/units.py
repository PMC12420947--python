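"""Unit conventions.

Everything internal is mm–Pa–s: lengths in mm, pressures in Pa, time in s.
Derived units then come out as flows in mm^3/s, conductances in mm^3/(Pa s),
permeabilities in mm^2/(Pa s) and coupling constants in 1/(Pa s).
mmHg and kPa are accepted at interfaces and converted here.
"""

MMHG_TO_PA = 133.322
KPA_TO_PA = 1000.0


def mmhg_to_pa(p_mmhg: float) -> float:
    return p_mmhg * MMHG_TO_PA


def pa_to_mmhg(p_pa: float) -> float:
    return p_pa / MMHG_TO_PA
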