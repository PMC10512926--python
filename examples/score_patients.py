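"""Score individual patients with the original and the locally modified index.

Shows the two risk conventions side by side: the original index takes the
single highest risk stratum, the modified index sums its local risk-factor
weights and multiplies by the creatinine injury score only.
"""

from renangia import PatientRecord, compute_mrai, compute_rai, mrai_local, rai_original

patient = PatientRecord(
    patient_id="example-1",
    age_years=2.0,
    sex="female",
    height_cm=85.0,
    weight_kg=12.0,
    diagnosis_category="sepsis",
    mechanical_ventilation_8h=True,
    vasopressor_support_8h=True,
    baseline_scr_umol_l=28.0,
    d0_scr_umol_l=47.6,        # 1.7x baseline -> creatinine injury score 4
    d3_scr_umol_l=64.4,
    fluid_in_l_8h=1.0,
    fluid_out_l_8h=0.6,        # %FO = 0.4/12*100 = 3.3% -> fluid score 1
)

rai = compute_rai(patient, rai_original())
print(f"original index: risk {rai.risk_score} x injury {rai.injury_score} "
      f"= {rai.rai} ({'positive' if rai.positive else 'negative'} at >= 8)")
print(f"  delta SCr {rai.delta_scr:.2f}, %FO {rai.percent_fo:.1f}%")

mrai = compute_mrai(patient, mrai_local())
print(f"modified index: risk sum {mrai.risk_score} x creatinine score "
      f"{mrai.injury_score} = {mrai.rai} "
      f"({'positive' if mrai.positive else 'negative'})")
# risk sum 16 = ICU (1) + sepsis (7) + ventilation&vasopressors (5) + age<=5 (3)
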