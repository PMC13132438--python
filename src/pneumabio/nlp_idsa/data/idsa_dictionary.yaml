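# Spanish criterion dictionary for the modified IDSA/ATS severity score.
#
# Patterns are regular expressions applied to NORMALISED text (lowercased,
# accents folded, punctuation runs collapsed to single spaces -- see
# nlp_idsa.normalise).  `plant_phrases` are literal realisations used by the
# synthetic corpus generator; every plant phrase must match one of the
# criterion's patterns after normalisation (enforced by tests).
#
# `context_rules` drive the V2 matcher: a criterion is additionally detected
# when the anchor and companion patterns co-occur within `max_distance`
# tokens.  Weights and the age component are configurable; the shipped
# defaults are unit weights with +1 for age >= 65.
#
# This dictionary is illustrative, assembled from criterion names and
# common clinical Spanish phrasing; it is not a transcript of any
# institution's production dictionary.

age_threshold: 65
age_points: 1

criteria:
  invasive_ventilation:
    weight: 1
    patterns:
      - 'ventilacion mecanica invasiva'
      - 'intubacion orotraqueal'
      - 'soporte ventilatorio invasivo'
      - '\bpaciente intubado\b'
    plant_phrases:
      - 'ventilacion mecanica invasiva'
      - 'intubacion orotraqueal'
      - 'soporte ventilatorio invasivo'
    context_rules:
      - anchor: '\bventilacion\b'
        companion: '\binvasiv[ao]\b'
        max_distance: 4

  septic_shock:
    weight: 1
    patterns:
      - 'choque septico'
      - 'shock septico'
      - 'soporte vasopresor'
      - 'requerimiento de vasopresores'
    plant_phrases:
      - 'choque septico'
      - 'shock septico'
      - 'requerimiento de vasopresores'
    context_rules:
      - anchor: '\bchoque\b'
        companion: '\bseptic[oa]\b'
        max_distance: 3

  tachypnea:
    weight: 1
    patterns:
      - '\btaquipnea\b'
      - '\bpolipnea\b'
    plant_phrases:
      - 'taquipnea'
      - 'polipnea'
    context_rules:
      - anchor: 'frecuencia respiratoria'
        companion: '\b(3[0-9]|[4-9][0-9])\b'
        max_distance: 5

  pao2_fio2:
    weight: 1
    patterns:
      - 'pao2/fio2 menor de 250'
      - 'relacion pao2/fio2 baja'
      - 'hipoxemia severa'
    plant_phrases:
      - 'pao2/fio2 menor de 250'
      - 'hipoxemia severa'
    context_rules:
      - anchor: '\bpafi\b|pao2/fio2'
        companion: '\b(\d{2}|1\d{2}|2[0-4]\d)\b'
        max_distance: 4

  multilobar_opacities:
    weight: 1
    patterns:
      - 'opacidades multilobares'
      - 'infiltrados multilobares'
      - 'compromiso multilobar'
      - 'infiltrados bilaterales'
    plant_phrases:
      - 'opacidades multilobares'
      - 'infiltrados multilobares'
      - 'infiltrados bilaterales'
    context_rules:
      - anchor: '\binfiltrados?\b|\bopacidades\b'
        companion: '\bmultilobar(es)?\b|\bbilaterales\b'
        max_distance: 4

  confusion:
    weight: 1
    patterns:
      - '\bconfusion\b'
      - '\bdesorientacion\b'
      - 'alteracion del estado de conciencia'
    plant_phrases:
      - 'confusion'
      - 'desorientacion'
      - 'alteracion del estado de conciencia'
    context_rules:
      - anchor: '\bestado de conciencia\b'
        companion: '\balterad[oa]\b|\balteracion\b'
        max_distance: 5

  uremia:
    weight: 1
    patterns:
      - '\buremia\b'
      - 'nitrogeno ureico elevado'
      - '\bbun elevado\b'
    plant_phrases:
      - 'uremia'
      - 'nitrogeno ureico elevado'
    context_rules:
      - anchor: '\bbun\b|\bnitrogeno ureico\b'
        companion: '\b([2-9]\d|[1-9]\d{2})\b'
        max_distance: 4

  leukopenia:
    weight: 1
    patterns:
      - '\bleucopenia\b'
      - 'leucocitos bajos'
    plant_phrases:
      - 'leucopenia'
      - 'leucocitos bajos'
    context_rules:
      - anchor: '\bleucocitos\b'
        companion: '\b[1-3]\d{3}\b'
        max_distance: 4

  hypotension:
    weight: 1
    patterns:
      - '\bhipotension\b'
      - 'presion arterial baja'
      - 'tension arterial baja'
    plant_phrases:
      - 'hipotension'
      - 'presion arterial baja'
    context_rules:
      - anchor: '\bpresion arterial\b|\btension arterial\b'
        companion: '\bbaja\b|\bdisminuida\b'
        max_distance: 4
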