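"""Generate a synthetic multicenter validation cohort and inspect it.

The default configuration reproduces the composition of a four-class
CSF-proteomics validation cohort: 65 RRMS, 31 progressive MS, 30
inflammatory and 34 non-inflammatory controls across three centers, with
SOMAscan-like protein profiles, EDSS timelines for the MS participants,
and conventional CSF markers (OCB, IgG index, sCD27, NFL).
"""

from mscsf.simulate import SimConfig, generate_cohort

cohort = generate_cohort(SimConfig(), seed=42)
parts = cohort.participants

print("cohort size:", len(parts))
print("by diagnosis:", parts["diagnosis"].value_counts().to_dict())
print("by center:", parts["center"].value_counts().sort_index().to_dict())
print("\nMS participants with follow-up EDSS:",
      parts["followup_edss"].notna().sum())
print("protein table shape:", cohort.proteomics.shape)
print("\nfirst rows:")
print(parts[["participant_id", "diagnosis", "age_at_lp", "sex",
             "baseline_edss", "followup_edss", "interval_years"]].head())

# The counts above are the study conditions every downstream example
# assumes: 96 MS vs 64 non-MS for diagnosis, 65 vs 31 for staging.
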