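{
  "description": "Registry of the 21 study-quality checklist items used to score clinical publications. Items are a hybrid of CAMARADES, Delphi risk-of-bias and GRADE criteria. Binary items score yes=1/no=0; tertiary items additionally allow not_clear=0.5; quinary items score definitely_yes=1, probably_yes=0.75, probably_no=0.25, definitely_no=0, with na excluded from scoring.",
  "items": [
    {"item_id": "peer_reviewed_publication", "label": "Peer reviewed publication", "response_class": "binary", "sources": ["CAMARADES"]},
    {"item_id": "conflict_of_interest_statement", "label": "Statement of potential conflicts of interest", "response_class": "binary", "sources": ["CAMARADES"]},
    {"item_id": "sample_size_calculation", "label": "Sample size calculation", "response_class": "binary", "sources": ["CAMARADES", "Delphi"]},
    {"item_id": "random_allocation", "label": "Random allocation to group", "response_class": "binary", "sources": ["CAMARADES", "Delphi", "GRADE"]},
    {"item_id": "allocation_concealment", "label": "Allocation concealment", "response_class": "binary", "sources": ["CAMARADES", "GRADE"]},
    {"item_id": "blinded_outcome_assessment", "label": "Blinded assessment of outcome", "response_class": "binary", "sources": ["Delphi"]},
    {"item_id": "baseline_similarity", "label": "Were the groups similar at baseline regarding the most important prognostic indicators?", "response_class": "tertiary", "sources": ["Delphi"]},
    {"item_id": "eligibility_criteria_specified", "label": "Were the eligibility criteria specified?", "response_class": "tertiary", "sources": ["Delphi"]},
    {"item_id": "point_estimates_variability", "label": "Were point estimates and measures of variability presented for the primary outcome measures?", "response_class": "tertiary", "sources": ["Delphi"]},
    {"item_id": "intention_to_treat", "label": "Was there intention to treat analysis?", "response_class": "tertiary", "sources": ["Delphi"]},
    {"item_id": "complete_outcome_accounting", "label": "Complete accounting of patient and outcome events", "response_class": "tertiary", "sources": ["GRADE"]},
    {"item_id": "nonselective_reporting", "label": "Non-selective outcome reporting", "response_class": "tertiary", "sources": ["Delphi"]},
    {"item_id": "no_other_limitations", "label": "No other limitations", "response_class": "tertiary", "sources": ["GRADE"]},
    {"item_id": "outcome_assessment_confidence", "label": "Can we be confident in the assessment of outcome?", "response_class": "tertiary", "sources": ["GRADE"]},
    {"item_id": "same_source_population", "label": "Was selection of treatment and control groups drawn from the same population?", "response_class": "quinary", "sources": ["GRADE"]},
    {"item_id": "treatment_adherence_confidence", "label": "Can we be confident that patients received the allocated treatment?", "response_class": "quinary", "sources": ["GRADE"]},
    {"item_id": "outcome_absent_at_start", "label": "Can we be confident that the outcome of interest was not present at start of the study?", "response_class": "quinary", "sources": ["GRADE"]},
    {"item_id": "stratified_prognostic_variables", "label": "Did the study stratify on variables associated with the outcome of interest or did the analysis take this into account?", "response_class": "quinary", "sources": ["GRADE"]},
    {"item_id": "prognostic_factor_assessment", "label": "Can we be confident in the assessment of the presence or absence of prognostic factors?", "response_class": "quinary", "sources": ["GRADE"]},
    {"item_id": "adequate_followup", "label": "Was the follow-up of cohorts adequate?", "response_class": "quinary", "sources": ["GRADE"]},
    {"item_id": "similar_cointerventions", "label": "Were cointerventions similar between groups?", "response_class": "quinary", "sources": ["GRADE"]}
  ]
}
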