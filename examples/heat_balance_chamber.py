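"""Partitional calorimetry of the chamber condition.

Computes the component heat fluxes for an adolescent walking at 60% of peak
aerobic power in 40 degC / 30% RH and reports the Ereq/Emax compensability
ratio (values above 1 mean sweating cannot fully balance the heat load).
"""

from heatadapt.calorimetry import Anthropometry, external_work, heat_balance, metabolic_rate

anthro = Anthropometry(mass_kg=56.84, height_m=1.70)
m = metabolic_rate(vo2_l_min=36.2 * 56.84 / 1000.0, rer=0.9)
w = external_work(56.84, speed_kmh=6.1, grade_pct=10.2)
hb = heat_balance(anthro, ta_c=40.0, rh_pct=30.0, tsk_c=36.3, m_rate_w=m, w_ext_w=w)

print(f"metabolic rate      {hb.m_rate:7.1f} W")
print(f"external work       {hb.w_ext:7.1f} W")
print(f"convective exchange {hb.conv:7.1f} W  (negative = dry heat gain)")
print(f"radiative exchange  {hb.rad:7.1f} W")
print(f"respiratory         {hb.c_res + hb.e_res:7.1f} W")
print(f"Ereq                {hb.e_req:7.1f} W")
print(f"Emax                {hb.e_max:7.1f} W")
print(f"Ereq/Emax           {hb.ratio:7.2f}   (> 1: uncompensable)")
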