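# Default exercise catalog: the seven-domain training battery of the
# Maintain Your Brain (MYB) Brain Training System, with the NeuroNation
# training exercises and the intake assessment mapped to each domain.
#
# Note on the exercise count: the system's prose description speaks of 34
# stand-alone exercises, but the published domain table enumerates 35
# exercise names.  This catalog ships the full 35-name enumeration, the only
# complete listing available; whether one table entry was merged or dropped
# in production is unknown, so the table is reproduced as printed.
#
# Visual Memory intake is measured by two instruments (Cogstate One Card
# Learning and Cambridge Brain Sciences Paired Associates) whose scores are
# combined into a single composite at intake, so the 8 baseline tests map
# onto 7 assessment records, one per domain.
exercises:
  - {id: memory_interrupted, name: "Memory interrupted", domain: "Verbal Memory"}
  - {id: memo_pair, name: "Memo pair", domain: "Verbal Memory"}
  - {id: verbal_learning, name: "Verbal learning", domain: "Verbal Memory"}
  - {id: eagle_eye, name: "Eagle eye", domain: "Visual Attention"}
  - {id: clockwise, name: "Clockwise", domain: "Visual Attention"}
  - {id: memobox, name: "Memobox", domain: "Visual Attention"}
  - {id: quick_count, name: "Quick count", domain: "Visual Attention"}
  - {id: quick_switch, name: "Quick switch", domain: "Visual Attention"}
  - {id: path_finder, name: "Path finder", domain: "Visual Memory"}
  - {id: path_finder_reverse, name: "Path finder reverse", domain: "Visual Memory"}
  - {id: restorer, name: "Restorer", domain: "Visual Memory"}
  - {id: focus_master, name: "Focus master", domain: "Visual Memory"}
  - {id: polaroid_picture, name: "Polaroid picture", domain: "Visual Memory"}
  - {id: symbolism, name: "Symbolism", domain: "Visual Memory"}
  - {id: turnabout, name: "Turnabout", domain: "Visual Memory"}
  - {id: reflector, name: "Reflector", domain: "Visual Memory"}
  - {id: word_craft, name: "Word craft", domain: "Verbal Executive"}
  - {id: scrambled_words, name: "Scrambled words", domain: "Verbal Executive"}
  - {id: domino_word, name: "Domino word", domain: "Verbal Executive"}
  - {id: password, name: "Password", domain: "Verbal Executive"}
  - {id: plastic_puzzle, name: "Plastic puzzle", domain: "Visual Executive"}
  - {id: solitaria, name: "Solitaria", domain: "Visual Executive"}
  - {id: escalator, name: "Escalator", domain: "Visual Executive"}
  - {id: color_craze, name: "Color craze", domain: "Visual Executive"}
  - {id: rotator, name: "Rotator", domain: "Visual Executive"}
  - {id: form_fusion, name: "Form fusion", domain: "Visual Executive"}
  - {id: missing_link, name: "Missing link", domain: "Visual Executive"}
  - {id: parita_speed, name: "Parita speed", domain: "Working Memory"}
  - {id: form_fever, name: "Form fever", domain: "Working Memory"}
  - {id: mixed_memories, name: "Mixed memories", domain: "Working Memory"}
  - {id: split_second, name: "Split second", domain: "Processing Speed"}
  - {id: flash_glance, name: "Flash glance", domain: "Processing Speed"}
  - {id: form_fever_speed, name: "Form fever speed", domain: "Processing Speed"}
  - {id: turning_tables, name: "Turning tables", domain: "Processing Speed"}
  - {id: alphabet_soup, name: "Alphabet soup", domain: "Processing Speed"}
assessments:
  - {id: logos, domain: "Verbal Memory", source: "LOGOS"}
  - {id: cogstate_identification, domain: "Visual Attention", source: "Cogstate - Identification"}
  - {id: visual_memory_composite, domain: "Visual Memory", source: "Cogstate - One card learning + Cambridge Brain Sciences - Paired associates (composite)"}
  - {id: cbs_grammatical_reasoning, domain: "Verbal Executive", source: "Cambridge Brain Sciences - Grammatical reasoning"}
  - {id: cbs_spatial_search, domain: "Visual Executive", source: "Cambridge Brain Sciences - Spatial search"}
  - {id: cogstate_one_back, domain: "Working Memory", source: "Cogstate - One-back test"}
  - {id: cogstate_detection, domain: "Processing Speed", source: "Cogstate - Detection"}
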