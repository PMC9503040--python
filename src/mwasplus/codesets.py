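"""Default diagnosis code sets.

Code-set membership is configuration, not science baked into the pipeline:
real deployments supply their own curated ICD lists via
:func:`mwasplus.data_model.load_codesets`.  The defaults below are small,
editable example sets covering the syndromic outcome (Alzheimer's disease
and related dementias), the dementias of known cause and severe psychiatric
conditions used for exclusion, the hyperlipidemia indication used by the
target-trial stage, and the comorbidity flags entering the propensity model.
They also match the codes emitted by the bundled synthetic generator.
"""

from __future__ import annotations

from mwasplus.data_model import CodeSet

#: Incident-outcome set: AD and related dementias, syndromically defined.
ADRD_OUTCOME = CodeSet.from_pairs("adrd_outcome", [
    ("ICD9", "331.0"),    # Alzheimer's disease
    ("ICD9", "290.0"), ("ICD9", "290.1"), ("ICD9", "290.2"), ("ICD9", "290.3"),
    ("ICD9", "294.1"),    # dementia in conditions classified elsewhere
    ("ICD10", "G30"),     # Alzheimer's disease
    ("ICD10", "F00"), ("ICD10", "F02"), ("ICD10", "F03"),
])

#: Dementias of known cause: carriers are excluded from the case series.
DEMENTIA_OTHER_CAUSES = CodeSet.from_pairs("dementia_other_causes", [
    ("ICD9", "290.4"),    # vascular dementia
    ("ICD9", "291.2"),    # alcohol-induced persisting dementia
    ("ICD9", "294.0"),    # amnestic disorder
    ("ICD10", "F01"),     # vascular dementia
    ("ICD10", "F10.27"),
])

#: Severe psychiatric conditions (schizophrenia, bipolar disorder).
SEVERE_PSYCHIATRIC = CodeSet.from_pairs("severe_psychiatric", [
    ("ICD9", "295"), ("ICD9", "296.0"), ("ICD9", "296.1"),
    ("ICD9", "296.4"), ("ICD9", "296.5"), ("ICD9", "296.6"), ("ICD9", "296.7"),
    ("ICD9", "296.8"),
    ("ICD10", "F20"), ("ICD10", "F25"), ("ICD10", "F31"),
])

#: Indication for the worked drug class (statins): hyperlipidemia.
HYPERLIPIDEMIA = CodeSet.from_pairs("hyperlipidemia", [
    ("ICD9", "272.0"), ("ICD9", "272.1"), ("ICD9", "272.2"), ("ICD9", "272.4"),
    ("ICD10", "E78.0"), ("ICD10", "E78.1"), ("ICD10", "E78.2"), ("ICD10", "E78.5"),
])

#: Comorbidity flag sets for the propensity-score covariate battery.
COMORBIDITIES: dict[str, CodeSet] = {
    "hypertension": CodeSet.from_pairs("hypertension", [
        ("ICD9", "401"), ("ICD10", "I10")]),
    "diabetes": CodeSet.from_pairs("diabetes", [
        ("ICD9", "250"), ("ICD10", "E11")]),
    "ischemic_heart_disease": CodeSet.from_pairs("ischemic_heart_disease", [
        ("ICD9", "410"), ("ICD9", "411"), ("ICD9", "412"), ("ICD9", "413"),
        ("ICD9", "414"), ("ICD10", "I20"), ("ICD10", "I21"), ("ICD10", "I25")]),
    "depression": CodeSet.from_pairs("depression", [
        ("ICD9", "311"), ("ICD10", "F32"), ("ICD10", "F33")]),
}

DEFAULT_CODESETS: dict[str, CodeSet] = {
    "adrd_outcome": ADRD_OUTCOME,
    "dementia_other_causes": DEMENTIA_OTHER_CAUSES,
    "severe_psychiatric": SEVERE_PSYCHIATRIC,
    "hyperlipidemia": HYPERLIPIDEMIA,
    **COMORBIDITIES,
}
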