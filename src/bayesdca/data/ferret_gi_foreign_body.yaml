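# Retrospective ferret gastrointestinal-foreign-body case, transcribed at
# printed precision from the published tables of the source case study.
# Composite probabilities are arithmetic means of three outside ferret
# clinicians' estimates, printed at one decimal; where full precision is
# needed (product columns), composites can be reconstructed as exact
# three-expert means with bayesdca.reconstruct_unrounded.
name: ferret-gi-foreign-body
description: >
  An approximately 1-year-old castrated male ferret presented emergently
  with two days of lethargy and anorexia and one day of diarrhea; the
  owners reported a habit of chewing objects. Abnormal findings included fever
  and a mildly enlarged left axillary lymph node; radiographs showed a
  moderately distended stomach with inhomogeneous soft-tissue opaque
  material and a non-radiologist ultrasound reported gastric foreign
  material. The clinical question is whether exploratory laparotomy for
  a suspected gastrointestinal foreign body was the optimal choice
  versus medical management.
metadata:
  species: ferret (Mustela putorius furo)
  panel: three outside clinicians with ferret expertise, surveyed independently
  utilities_panel: three members of the original clinical team
diagnoses:
  - Lymphoma
  - GI Foreign Body
  - Systemic Coronaviral Infection
  - Helicobacter Gastritis
  - Disseminated Idiopathic Myofasciitis
  - Bacterial Gastroenteritis
  - Unknown Toxicosis
priors:
  provenance: composite
  values:
    Lymphoma: 9.3
    GI Foreign Body: 46.7
    Systemic Coronaviral Infection: 5.3
    Helicobacter Gastritis: 10.7
    Disseminated Idiopathic Myofasciitis: 7.7
    Bacterial Gastroenteritis: 18.3
    Unknown Toxicosis: 2.7
stages:
  - name: pre-surgical
    findings: [Physical Exam, Radiography, Ultrasonography, CBC, Chemistry]
    conditionals:
      Lymphoma:
        {Physical Exam: 25, Radiography: 25, Ultrasonography: 11.7, CBC: 35, Chemistry: 30}
      GI Foreign Body:
        {Physical Exam: 20, Radiography: 20, Ultrasonography: 43.3, CBC: 35, Chemistry: 15.3}
      Systemic Coronaviral Infection:
        {Physical Exam: 8.3, Radiography: 18.3, Ultrasonography: 5.3, CBC: 23.7, Chemistry: 18.3}
      Helicobacter Gastritis:
        {Physical Exam: 8.3, Radiography: 28.3, Ultrasonography: 23.3, CBC: 30, Chemistry: 41.7}
      Disseminated Idiopathic Myofasciitis:
        {Physical Exam: 43.3, Radiography: 21.7, Ultrasonography: 13.7, CBC: 46.7, Chemistry: 20}
      Bacterial Gastroenteritis:
        {Physical Exam: 27, Radiography: 28.3, Ultrasonography: 32, CBC: 46.7, Chemistry: 35}
      Unknown Toxicosis:
        {Physical Exam: 10.3, Radiography: 21.7, Ultrasonography: 26.7, CBC: 27, Chemistry: 18.7}
  - name: post-surgical
    findings: [Exploratory Laparotomy, Lymph Node Cytology, Clinical Progression]
    conditionals:
      Lymphoma:
        {Exploratory Laparotomy: 23.7, Lymph Node Cytology: 35, Clinical Progression: 15}
      GI Foreign Body:
        {Exploratory Laparotomy: 12, Lymph Node Cytology: 6.7, Clinical Progression: 11.7}
      Systemic Coronaviral Infection:
        {Exploratory Laparotomy: 7, Lymph Node Cytology: 11.7, Clinical Progression: 13.3}
      Helicobacter Gastritis:
        {Exploratory Laparotomy: 60, Lymph Node Cytology: 6.1, Clinical Progression: 19.3}
      Disseminated Idiopathic Myofasciitis:
        {Exploratory Laparotomy: 12, Lymph Node Cytology: 6.1, Clinical Progression: 55}
      Bacterial Gastroenteritis:
        {Exploratory Laparotomy: 51.7, Lymph Node Cytology: 6.1, Clinical Progression: 30.7}
      Unknown Toxicosis:
        {Exploratory Laparotomy: 8.7, Lymph Node Cytology: 5.3, Clinical Progression: 13.3}
decision:
  disease: GI Foreign Body
  treat_label: surgery
  no_treat_label: no surgery
  utilities:
    experts:
      - {treated_disease: 90, treated_no_disease: 70, untreated_disease: 25, untreated_no_disease: 100}
      - {treated_disease: 80, treated_no_disease: 60, untreated_disease: 25, untreated_no_disease: 100}
      - {treated_disease: 80, treated_no_disease: 50, untreated_disease: 20, untreated_no_disease: 100}
    composite:
      {treated_disease: 83.3, treated_no_disease: 60, untreated_disease: 23.3, untreated_no_disease: 100}
reference:
  note: >
    Published values at printed precision, kept for provenance and
    integrity checks. Product columns were computed from unrounded
    three-expert means; posteriors are printed to whole percents except
    where a smaller value forced more decimals.
  pre_surgical:
    products:
      Lymphoma: 71458333
      GI Foreign Body: 434103704
      Systemic Coronaviral Infection: 1885542
      Helicobacter Gastritis: 73456790
      Disseminated Idiopathic Myofasciitis: 91816379
      Bacterial Gastroenteritis: 733040000
      Unknown Toxicosis: 8024178
    products_sum: 1413784925
    posteriors:
      Lymphoma: 5
      GI Foreign Body: 31
      Systemic Coronaviral Infection: 0.1
      Helicobacter Gastritis: 5
      Disseminated Idiopathic Myofasciitis: 6
      Bacterial Gastroenteritis: 52
      Unknown Toxicosis: 1
  at_euthanasia:
    priors_display:
      Lymphoma: 5
      GI Foreign Body: 31
      Systemic Coronaviral Infection: 0.1
      Helicobacter Gastritis: 5
      Disseminated Idiopathic Myofasciitis: 6
      Bacterial Gastroenteritis: 52
      Unknown Toxicosis: 1
    products:
      Lymphoma: 62801
      GI Foreign Body: 28658
      Systemic Coronaviral Infection: 145
      Helicobacter Gastritis: 36966
      Disseminated Idiopathic Myofasciitis: 26146
      Bacterial Gastroenteritis: 501131
      Unknown Toxicosis: 350
    products_sum: 656197
    posteriors:
      Lymphoma: 10
      GI Foreign Body: 4
      Systemic Coronaviral Infection: 0.02
      Helicobacter Gastritis: 6
      Disseminated Idiopathic Myofasciitis: 4
      Bacterial Gastroenteritis: 76
      Unknown Toxicosis: 0.05
  decision:
    expected_value_treat: 67
    expected_value_no_treat: 76
    threshold_composite_pct: 40
    thresholds_experts_pct: [32, 42, 45]
  counterfactual_ultrasound_only:
    GI Foreign Body: 64
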