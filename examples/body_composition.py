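"""Derive body composition from one bioimpedance measurement."""

from glycotrial import body_composition

# a 175 cm, 90 kg male with resistance 480 ohm and reactance 50 ohm
bc = body_composition("male", height=175, weight=90, resistance=480, reactance=50)

print(f"fat-free mass {bc.ffm:.2f} kg   total body water {bc.tbw:.2f} kg")
print(f"fat mass      {bc.fm:.2f} kg ({bc.fat_pct:.1f}% of body weight)")
print(f"muscle mass   {bc.mm:.2f} kg ({bc.muscle_pct:.1f}%)")
print("-> FM + FFM equals body weight exactly; muscle is 64% of FFM after")
print("   removing extracellular water (29%) and bone mineral (7%).")
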