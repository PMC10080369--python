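{
  "version": "default-1",
  "rules": [
    {
      "id": "explicit_accident",
      "kind": "explicit_intent",
      "intent": "accident",
      "predicate": {"op": "require_category", "category": "explicit_intent_accident",
                    "forbid_modifiers": ["negated", "historical", "other_subject"]}
    },
    {
      "id": "explicit_assault",
      "kind": "explicit_intent",
      "intent": "assault",
      "predicate": {"op": "require_category", "category": "explicit_intent_assault",
                    "forbid_modifiers": ["negated", "historical", "other_subject"]}
    },
    {
      "id": "explicit_self_harm",
      "kind": "explicit_intent",
      "intent": "self_harm",
      "predicate": {"op": "require_category", "category": "explicit_intent_self_harm",
                    "forbid_modifiers": ["negated", "historical", "other_subject"]}
    },
    {
      "id": "explicit_legal",
      "kind": "explicit_intent",
      "intent": "legal_intervention",
      "predicate": {"op": "require_category", "category": "explicit_intent_legal",
                    "forbid_modifiers": ["negated", "historical", "other_subject"]}
    },
    {
      "id": "no_info_attestation",
      "kind": "explicit_intent",
      "intent": "unknown",
      "predicate": {"op": "require_category", "category": "no_info_attestation",
                    "forbid_modifiers": ["negated", "historical", "other_subject"]}
    },
    {
      "id": "assault_shooter",
      "kind": "role",
      "predicate": {"op": "event_role", "role": "shooter",
                    "exclude": ["self", "police", "nonperson"]}
    },
    {
      "id": "legal_shooter",
      "kind": "role",
      "predicate": {"op": "event_role", "role": "shooter",
                    "match_category": "police_actor"}
    },
    {
      "id": "self_directed_shot",
      "kind": "role",
      "predicate": {"op": "event_flag", "flag": "self_directed"}
    },
    {
      "id": "location_inside",
      "kind": "location",
      "predicate": {"op": "require_tag", "category": "incident_location",
                    "tag": "location", "value": "inside"}
    },
    {
      "id": "location_outside",
      "kind": "location",
      "predicate": {"op": "require_tag", "category": "incident_location",
                    "tag": "location", "value": "outside"}
    },
    {
      "id": "high_info_note",
      "kind": "info_density",
      "predicate": {"op": "pair_count", "scope": "per_note_max", "cmp": "ge",
                    "threshold": "high_info_threshold"}
    },
    {
      "id": "low_info_case",
      "kind": "info_density",
      "predicate": {"op": "pair_count", "scope": "per_case", "cmp": "lt",
                    "threshold": "low_info_threshold"}
    },
    {
      "id": "no_explicit_intent",
      "kind": "meta",
      "predicate": {"op": "count_explicit", "cmp": "eq", "value": 0}
    },
    {
      "id": "conflicting_intent",
      "kind": "meta",
      "predicate": {"op": "distinct_explicit_intents", "cmp": "ge", "value": 2}
    }
  ]
}
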