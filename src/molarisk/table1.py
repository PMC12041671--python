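"""Published case series: the 31 patients who developed GTN after hCG normalisation.

Each tuple is (patient_id, days evacuation->first normal hCG, days first normal
hCG->treatment start, presentation tags, FIGO score, treatment text,
intervening pregnancies (None = unknown), genetics).  Presentation free text
was tokenised once into the controlled tag vocabulary; descriptive wording
that falls outside it (choriocarcinoma on pathology, uterine mass, shock,
amenorrhoea, neurological symptoms, ...) is tagged ``other``.
"""

from .cohort import Genetics, Outcome, PatientRecord

_M = Genetics.MATCHED_ORIGINAL
_I = Genetics.INVASIVE_CHM_RELAPSE_ONLY
_U = Genetics.UNKNOWN

# fmt: off
_ROWS = [
    # --- hCG normalisation in <56 days ---
    ("1", 41, 360, {"abdominal_pain", "other"}, 5,
     "Hysterectomy followed by EMACO×4", 0, _M),
    ("2", 47, 114, {"raised_hcg", "other"}, 4,
     "MTX×7", 0, _U),
    ("3", 55, 1209, {"abdominal_pain", "lung_met", "brain_met", "other"}, 11,
     "High dose EMACO×6 and IT MTX×6", None, _U),
    # --- hCG normalisation in >=56 days ---
    ("4", 61, 1334, {"abdominal_pain", "raised_hcg", "lung_met", "other"}, 10,
     "EP induction then EMACO×8 with IT MTX×1", None, _U),
    ("5", 65, 76, {"raised_hcg"}, 2,
     "MTX×6", 0, _U),
    ("6", 81, 37, {"raised_hcg"}, 2,
     "MTX×1 switched to EMACO×7 because of steep increase in hCG", 0, _U),
    ("7", 83, 2697, {"vaginal_bleeding", "vaginal_met", "other"}, 8,
     "EMACO×9", 1, _U),
    ("8", 88, 279, {"unknown"}, 4,
     "EP×2, HuMMp×5", None, _U),
    ("9", 90, 66, {"vaginal_bleeding", "raised_hcg"}, 5,
     "MTX×2, switched to EMACO×3 followed by hysterectomy", 0, _U),
    ("10", 96, 438, {"unknown"}, 7,
     "EMACO×10", None, _U),
    ("11", 105, 875, {"raised_hcg", "other"}, 7,
     "MTX×4 switched to Dact×5 because of plateau and then EMACO×5", 1, _U),
    ("12", 105, 1072, {"raised_hcg", "other"}, 5,
     "MTX then IVA. Subsequent relapse 20 days after treatment completion. "
     "Declined subsequent treatment until stage IV disease then treated with "
     "induction EP, EMAEP, Pembro, and TETP", 0, _U),
    ("13", 108, 739, {"unknown"}, 6,
     "EP×2 and HuMMP×3. Subsequent relapse 44 days after treatment "
     "completion, treated with EMACO×8", None, _U),
    ("14", 109, 138, {"raised_hcg"}, 3,
     "MTX×2, switched to VAC×3", 0, _U),
    ("15", 115, 207, {"raised_hcg"}, 6,
     "MTX×2 switched to EP×4, switched to EMACO×2, switched to "
     "EMAEP×6 with hysterectomy in between", 0, _M),
    ("16", 115, 290, {"raised_hcg", "lung_met"}, 3,
     "EMAEP×2, followed by hysterectomy and thoracotomy, followed by TETP×2", 1, _I),
    ("17", 116, 215, {"unknown"}, 5,
     "EP and HuMMp×3", None, _U),
    ("18", 121, 132, {"vaginal_bleeding", "raised_hcg", "brain_met"}, 10,
     "EMACO×9 with IT MTX×3", 0, _M),
    ("19", 126, 516, {"raised_hcg"}, 4,
     "MTX×3 switched to Dact×4 because of plateau", 0, _U),
    ("20", 127, 267, {"raised_hcg", "other"}, 7,
     "Hysterectomy", 0, _I),
    ("21", 131, 60, {"raised_hcg"}, 2,
     "EMACO×6", 0, _U),
    ("22", 133, 677, {"vaginal_bleeding", "raised_hcg"}, 7,
     "EMACO×9. Had a subsequent relapse 8 months after, treated with EMAEP "
     "and thoracotomy", None, _U),
    ("23", 140, 878, {"vaginal_bleeding", "brain_met", "lung_met", "kidney_met", "other"}, 18,
     "Induction EP, craniotomy for subarachnoid haemorrhage, high dose EMACO×7 "
     "and IT MTX×5", 1, _U),
    ("24", 141, 4, {"raised_hcg"}, 2,
     "MTX×5", 0, _U),
    ("25", 151, 373, {"unknown"}, 6,
     "EP×2, switched to EMACO×2, CHAMOCA×2, EP×1", None, _U),
    ("26", 152, 91, {"raised_hcg"}, 2,
     "EMACO×6", 0, _U),
    ("27", 174, 493, {"vaginal_bleeding", "lung_met", "brain_met"}, 9,
     "EP induction then EMACO×6 with IT MTX×4", 0, _U),
    ("28", 174, 2073, {"vaginal_bleeding", "vaginal_met", "other"}, 11,
     "EP induction then EMACO×5 with IT MTX×3", None, _U),
    ("29", 194, 1765, {"vaginal_bleeding", "raised_hcg", "other"}, 9,
     "EMACO×7 switched to EMAEP×6", 1, _U),
    ("30", 222, 953, {"vaginal_bleeding", "raised_hcg", "other"}, 5,
     "Uterine evacuation, patient declined chemotherapy", None, _M),
    ("31", 306, 371, {"raised_hcg"}, 4,
     "MTX×4, switched to EMACO×5. Subsequent relapse 41 days after "
     "treatment completion, treated with hysterectomy and EMAEP×2", 0, _U),
]
# fmt: on

TABLE1_RECORDS = tuple(
    PatientRecord(
        patient_id=pid,
        days_evac_to_normal=d_norm,
        outcome=Outcome.GTN,
        days_normal_to_end=d_treat,
        presentation_tags=frozenset(tags),
        treatment_text=treatment,
        n_interval_pregnancies=pregnancies,
        genetics=genetics,
        figo_score=figo,
    )
    for pid, d_norm, d_treat, tags, figo, treatment, pregnancies, genetics in _ROWS
)
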