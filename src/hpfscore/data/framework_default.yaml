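# Default hierarchical structure of the Aboriginal and Torres Strait Islander
# Health Performance Framework: 3 tiers, 15 groups, 68 measures.
tiers:
  - number: 1
    name: Health status and outcomes
    groups:
      - name: Health conditions
        measures:
          - "1.01 Low birth weight"
          - "1.02 Top reasons for hospitalisation"
          - "1.03 Injury and poisoning"
          - "1.04 Respiratory disease"
          - "1.05 Circulatory disease"
          - "1.06 Acute rheumatic fever and rheumatic heart disease"
          - "1.07 High blood pressure"
          - "1.08 Cancer"
          - "1.09 Diabetes"
          - "1.10 Kidney disease"
          - "1.11 Oral health"
          - "1.12 HIV/AIDS, hepatitis, and sexually transmissible infections"
      - name: Human function
        measures:
          - "1.13 Community functioning"
          - "1.14 Disability"
          - "1.15 Ear health"
          - "1.16 Eye health"
      - name: Life expectancy and wellbeing
        measures:
          - "1.17 Perceived health status"
          - "1.18 Social and emotional wellbeing"
          - "1.19 Life expectancy at birth"
      - name: Deaths
        measures:
          - "1.20 Infant and child mortality"
          - "1.21 Perinatal mortality"
          - "1.22 All-causes age-standardised death rates"
          - "1.23 Leading causes of mortality"
          - "1.24 Avoidable and preventable deaths"
  - number: 2
    name: Determinants of health
    groups:
      - name: Environmental factors
        measures:
          - "2.01 Housing"
          - "2.02 Access to functional housing with utilities"
          - "2.03 Environmental tobacco smoke"
      - name: Socio-economic factors
        measures:
          - "2.04 Literacy and numeracy"
          - "2.05 Education outcomes for young people"
          - "2.06 Educational participation and attainment of adults"
          - "2.07 Employment"
          - "2.08 Income"
          - "2.09 Index of disadvantage"
      - name: Community capacities
        measures:
          - "2.10 Community safety"
          - "2.11 Contact with the criminal justice system"
          - "2.12 Child protection"
          - "2.13 Transport"
          - "2.14 Indigenous people with access to their traditional lands"
      - name: Health behaviours
        measures:
          - "2.15 Tobacco use"
          - "2.16 Risky alcohol consumption"
          - "2.17 Drug and other substance use including inhalants"
          - "2.18 Physical activity"
          - "2.19 Dietary behaviour"
          - "2.20 Breastfeeding practices"
          - "2.21 Health behaviours during pregnancy"
      - name: Person-related factor
        measures:
          - "2.22 Overweight and obesity"
  - number: 3
    name: Health system performance
    groups:
      - name: Effective, appropriate, efficient
        measures:
          - "3.01 Antenatal care"
          - "3.02 Immunisation"
          - "3.03 Health promotion"
          - "3.04 Early detection and early treatment"
          - "3.05 Chronic disease management"
          - "3.06 Access to hospital procedures"
          - "3.07 Selected potentially preventable hospital admissions"
          - "3.08 Cultural competency"
      - name: Responsive
        measures:
          - "3.09 Discharge against medical advice"
          - "3.10 Access to mental-health services"
          - "3.11 Access to alcohol and drug services"
          - "3.12 Aboriginal and Torres Strait Islander people in the health workforce"
          - "3.13 Competent governance"
      - name: Accessible
        measures:
          - "3.14 Access to services compared with need"
          - "3.15 Access to prescription medicines"
          - "3.16 Access to after-hours primary health care"
      - name: Continuous
        measures:
          - "3.17 Regular general practitioner or health service"
          - "3.18 Care planning for chronic diseases"
      - name: Capable
        measures:
          - "3.19 Accreditation"
          - "3.20 Aboriginal and Torres Strait Islander people training for health-related disciplines"
      - name: Sustainable
        measures:
          - "3.21 Expenditure on Aboriginal and Torres Strait Islander health compared with need"
          - "3.22 Recruitment and retention of staff"
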