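"""Hemoglobin mass and intravascular volumes from a CO-rebreathing record.

Builds a noiseless rebreathing record from known hematology (690 g Hb,
4500 mL blood volume) and inverts it: the recovered Hb mass matches the
truth exactly, and the volume decomposition follows.
"""

from heatadapt.hematology import hb_mass_from_rebreathe, intravascular_volumes
from heatadapt.synthetic import generate_co_rebreathe

rec = generate_co_rebreathe(hb_mass_true_g=690.0, blood_volume_true_ml=4500.0,
                            body_mass_kg=56.84)
hb = hb_mass_from_rebreathe(rec)
vols = intravascular_volumes(hb, rec.hct, rec.hb_conc_g_dl, rec.body_mass_kg)

print(f"administered CO   {rec.co_admin_ml:6.1f} mL (0.8 mL/kg)")
print(f"HbCO rise         {rec.hbco_post_pct - rec.hbco_pre_pct:6.2f} %-points")
print(f"Hb mass           {hb:6.1f} g   ({vols.hb_mass_g_kg:.1f} g/kg)")
print(f"blood volume      {vols.blood_volume_ml:6.0f} mL ({vols.blood_volume_ml_kg:.1f} mL/kg)")
print(f"plasma volume     {vols.plasma_volume_ml:6.0f} mL ({vols.plasma_volume_ml_kg:.1f} mL/kg)")
# Plasma-volume expansion over summer would indicate hematological adaptation;
# per-kg values are what pre/post contrasts are computed on.
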