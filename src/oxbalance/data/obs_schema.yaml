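# Default oxidative balance score (OBS) assignment scheme.
#
# 20 components: 16 dietary (14 antioxidant + 2 prooxidant) and 4 lifestyle
# (1 antioxidant + 3 prooxidant).  Every component except alcohol is scored
# against sex-specific tertile cutpoints [t1, t2] in the component's own
# units; alcohol uses fixed heavy-drinking thresholds by sex.
version: nhanes-1999-2002
alcohol_rule:
  male_threshold_g_per_day: 30.0
  female_threshold_g_per_day: 15.0
components:
  - name: fiber
    group: dietary
    polarity: antioxidant
    rule: sex_tertile
    units: g/d
    cutpoints:
      male: [12.56, 19.70]
      female: [10.10, 16.31]
  - name: carotene
    group: dietary
    polarity: antioxidant
    rule: sex_tertile
    units: RE/d
    cutpoints:
      male: [98.83, 306.25]
      female: [98.08, 383.50]
  - name: riboflavin
    group: dietary
    polarity: antioxidant
    rule: sex_tertile
    units: mg/d
    cutpoints:
      male: [1.79, 2.69]
      female: [1.34, 2.02]
  - name: niacin
    group: dietary
    polarity: antioxidant
    rule: sex_tertile
    units: mg/d
    cutpoints:
      male: [20.65, 29.75]
      female: [14.52, 21.86]
  - name: vitamin_b6
    group: dietary
    polarity: antioxidant
    rule: sex_tertile
    units: mg/d
    cutpoints:
      male: [1.59, 2.40]
      female: [1.13, 1.77]
  - name: total_folate
    group: dietary
    polarity: antioxidant
    rule: sex_tertile
    units: mcg/d
    cutpoints:
      male: [316.00, 492.00]
      female: [251.00, 388.96]
  - name: vitamin_b12
    group: dietary
    polarity: antioxidant
    rule: sex_tertile
    units: mcg/d
    cutpoints:
      male: [3.36, 6.20]
      female: [2.22, 4.22]
  - name: vitamin_c
    group: dietary
    polarity: antioxidant
    rule: sex_tertile
    units: mg/d
    cutpoints:
      male: [42.44, 113.21]
      female: [38.01, 98.49]
  - name: vitamin_e
    group: dietary
    polarity: antioxidant
    rule: sex_tertile
    units: ATE mg/d
    cutpoints:
      male: [5.82, 9.42]
      female: [4.53, 7.52]
  - name: calcium
    group: dietary
    polarity: antioxidant
    rule: sex_tertile
    units: mg/d
    cutpoints:
      male: [646.00, 1072.00]
      female: [499.24, 849.00]
  - name: magnesium
    group: dietary
    polarity: antioxidant
    rule: sex_tertile
    units: mg/d
    cutpoints:
      male: [257.00, 361.28]
      female: [187.00, 283.43]
  - name: zinc
    group: dietary
    polarity: antioxidant
    rule: sex_tertile
    units: mg/d
    cutpoints:
      male: [9.75, 15.10]
      female: [6.73, 10.75]
  - name: copper
    group: dietary
    polarity: antioxidant
    rule: sex_tertile
    units: mg/d
    cutpoints:
      male: [1.12, 1.57]
      female: [0.85, 1.28]
  - name: selenium
    group: dietary
    polarity: antioxidant
    rule: sex_tertile
    units: mcg/d
    cutpoints:
      male: [94.94, 141.80]
      female: [67.79, 99.50]
  - name: total_fat
    group: dietary
    polarity: prooxidant
    rule: sex_tertile
    units: g/d
    cutpoints:
      male: [69.83, 107.43]
      female: [50.98, 75.79]
  - name: iron
    group: dietary
    polarity: prooxidant
    rule: sex_tertile
    units: mg/d
    cutpoints:
      male: [12.88, 19.17]
      female: [9.65, 14.32]
  - name: physical_activity
    group: lifestyle
    polarity: antioxidant
    rule: sex_tertile
    units: MET-min/week
    cutpoints:
      male: [417.86, 1135.71]
      female: [270.00, 845.71]
  - name: alcohol
    group: lifestyle
    polarity: prooxidant
    rule: fixed_alcohol
    units: g/d
  - name: bmi
    group: lifestyle
    polarity: prooxidant
    rule: sex_tertile
    units: kg/m^2
    cutpoints:
      male: [25.54, 29.17]
      female: [23.74, 28.64]
  - name: cotinine
    group: lifestyle
    polarity: prooxidant
    rule: sex_tertile
    units: ng/mL
    cutpoints:
      male: [0.038, 1.13]
      female: [0.035, 0.172]
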