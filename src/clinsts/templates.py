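"""Template bank for the synthetic clinical sentence-pair generator.

Three registers echo the style of clinical note sentences: symptom
documentation, medication instructions, and patient education.  Templates
are clause lists; the ``<n>`` placeholder is filled with a sampled number so
the number-similarity feature is exercised, and many templates embed phrases
from the bundled concept lexicon so the entity feature is exercised too.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class Template:
    register: str
    clauses: tuple[str, ...]


def _t(register: str, *clauses: str) -> Template:
    return Template(register, tuple(clauses))


TEMPLATE_BANK: tuple[Template, ...] = (
    # -- symptom documentation -------------------------------------------
    _t("symptom", "the patient denies chest pain and shortness of breath",
       "symptoms are constant"),
    _t("symptom", "gradual onset of symptoms",
       "there has been no change in the patient's symptoms over time"),
    _t("symptom", "the patient reports nausea and vomiting for <n> days"),
    _t("symptom", "historian denies abdominal pain",
       "negative gastrointestinal review of systems"),
    _t("symptom", "the patient complains of headache and dizziness since this morning"),
    _t("symptom", "negative ears nose throat review of systems",
       "historian denies otalgia and sore throat"),
    _t("symptom", "the patient presents with fever of <n> degrees and cough"),
    _t("symptom", "mild swelling of the left ankle noted on exam"),
    _t("symptom", "the patient reports fatigue and back pain for the past <n> weeks"),
    _t("symptom", "no rash or wheezing was observed during the visit"),
    _t("symptom", "palpitations occur intermittently and resolve with rest"),
    _t("symptom", "blood pressure was <n> over 80 and heart rate was 72"),
    _t("symptom", "the patient denies constipation and diarrhea"),
    _t("symptom", "sudden onset of symptoms", "onset was <n> hours ago"),
    _t("symptom", "the patient reports chest pain radiating to the left arm"),
    _t("symptom", "asthma symptoms are well controlled on current therapy"),
    _t("symptom", "hypertension and diabetes are stable on current medications"),
    # -- medication instructions -----------------------------------------
    _t("medication", "take <n> tablets of metformin 500 mg by mouth twice daily"),
    _t("medication", "apply hydrocortisone cream 1 topically three times a day as needed"),
    _t("medication", "take ibuprofen <n> mg every six hours as needed for pain"),
    _t("medication", "inject <n> units of insulin before breakfast each morning"),
    _t("medication", "take aspirin 81 mg by mouth once daily"),
    _t("medication", "take lisinopril <n> mg daily for blood pressure control"),
    _t("medication", "take amoxicillin 500 mg three times daily for <n> days"),
    _t("medication", "use the albuterol inhaler two puffs every four hours as needed for wheezing"),
    _t("medication", "take acetaminophen <n> mg every four hours as needed for fever"),
    _t("medication", "resume all home medications after the procedure"),
    _t("medication", "hold metformin for <n> days after the contrast study"),
    # -- patient education ------------------------------------------------
    _t("education", "please call the clinic if you develop fever over <n> degrees"),
    _t("education", "the patient understands the information and wishes to proceed with the biopsy"),
    _t("education", "the procedure risks and alternatives were discussed in detail with the patient"),
    _t("education", "patient will demonstrate understanding of home exercise program following this therapy session"),
    _t("education", "patient stated understanding of the program and was receptive to modifying activities"),
    _t("education", "no barriers to learning were identified"),
    _t("education", "the patient was instructed to follow up in <n> weeks"),
    _t("education", "continue physical therapy sessions twice weekly for <n> weeks"),
    _t("education", "the patient verbalized understanding of all discharge instructions"),
    _t("education", "questions were answered and the patient agreed with the plan of care"),
    _t("education", "the patient was advised to rest and drink plenty of fluids"),
    _t("education", "diabetes education materials were provided to the patient"),
    _t("education", "the patient was counseled on the importance of medication adherence"),
    _t("education", "return to the emergency department if symptoms worsen"),
)

#: Single-token synonym substitutions used by the light perturbation bands.
SYNONYMS: dict[str, str] = {
    "daily": "everyday",
    "mild": "slight",
    "sudden": "abrupt",
    "gradual": "slow",
    "constant": "persistent",
    "reports": "describes",
    "denies": "refutes",
    "understands": "comprehends",
    "instructed": "told",
    "advised": "counseled",
    "develop": "experience",
    "call": "phone",
    "clinic": "office",
    "noted": "observed",
    "worsen": "increase",
    "stated": "expressed",
    "wishes": "wants",
    "discussed": "reviewed",
    "provided": "given",
    "continue": "maintain",
    "occur": "happen",
    "complains": "reports",
    "resume": "restart",
    "demonstrate": "show",
}

#: Values used to fill the ``<n>`` number placeholder.
NUMBER_CHOICES: tuple[int, ...] = (1, 2, 3, 4, 5, 6, 7, 8, 10, 12, 14, 20, 100, 101, 120)
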