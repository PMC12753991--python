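# Declarative rule base for health-education resource generation.
# Modality rules are evaluated in descending priority; the first match wins.
# Content rules all fire independently and are logged in provenance.

modality_rules:
  - id: topic_virology_age60
    priority: 100
    when: {topic: virological_characteristics, min_age: 60}
    formats: [video, audio_narration]
  - id: age60_default
    priority: 50
    when: {min_age: 60}
    formats: [audio_narration, large_font_text]
  - id: low_education
    priority: 40
    when: {education: below_high_school}
    formats: [short_video, infographic]
  - id: universal_default
    priority: 0
    when: {}
    formats: [interactive_qa, long_form_text]

content_rules:
  - id: card_lianhua_qingwen
    when_entity: lianhua_qingwen
    kind: knowledge_card
    card_text: "Usage: Symptom relief only; not for prevention."
  - id: card_omicron
    when_entity: omicron_variant
    kind: knowledge_card
    card_text: >-
      The Omicron variant spreads mainly through the air; masks and
      ventilation remain the core defences.
  - id: linkout_omicron
    when_entity: omicron_variant
    kind: link_out
    target: variant_science_page
    text: "Learn more on the dedicated variant science page."
  - id: chart_vaccine_efficacy
    when_rule_item: vaccine_efficacy
    kind: comparative_chart
    text: "Comparative chart: protection levels by vaccine dose and variant."
  - id: alert_gatherings_no_mask
    when_items_present: [mass_gatherings]
    when_items_absent: [mask_wearing]
    kind: risk_alert
    text: >-
      Risk alert: mass gatherings mentioned without mask guidance — always
      wear a mask in crowded settings.

frameworks:
  preventive_measures:
    - personal_protection
    - community_management
    - travel_policies
  virological_characteristics: [variant_overview, transmission_science]
  case_data: [situation_summary, trend_reading]
  medical_resources: [access_guide, service_hours]
  science_communication: [myth_busting, evidence_levels]

default_citation: "Source: National Health Commission bulletin"
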