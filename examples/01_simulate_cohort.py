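"""Simulate a small PPG cohort and look at its ground truth.

Generates a 12-subject cohort (two per class) of 30-second pulse-oximeter
recordings at 120 Hz, with class-conditional pulse morphology: healthy
subjects carry a clear diastolic wave, disease classes an attenuated or
absent one.
"""

from ppgscreen.synthgen import CLASS_LABELS, GeneratorConfig, generate_cohort

config = GeneratorConfig(
    n_per_class={label: 2 for label in CLASS_LABELS},
    duration=30.0,
    seed=7,
)
cohort = generate_cohort(config)

table = cohort.subject_table()
print(f"{len(cohort)} subjects, {config.duration:.0f} s each at {config.fs:.0f} Hz")
print(table[["subject_id", "label", "age", "spo2", "pulse_rate"]].to_string(index=False))

truth = cohort.ground_truth_table()
notch_rate = truth.groupby(
    truth["subject_id"].map(dict(zip(table["subject_id"], table["label"])))
)["t_notch"].apply(lambda s: s.notna().mean())
print("\nFraction of beats with a true dicrotic notch, by class:")
print(notch_rate.round(2).to_string())
print(
    "\nDisease classes show attenuated/absent notches - the morphological"
    "\nsignal the downstream screen exploits."
)
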