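{
  "description": "Synthetic stand-in lexicon of category-typical clinical vocabulary for IBD secure messaging. Authored for this package; not derived from any study's keyword list. Codes are the final eight-category scheme with miscellaneous as the fallback.",
  "categories": [
    {
      "code": 1,
      "name": "symptoms",
      "keywords": [
        "pain", "abdominal pain", "cramping", "diarrhea", "bleeding",
        "nausea", "vomiting", "fatigue", "flare", "bloating", "fever",
        "stool", "urgency"
      ]
    },
    {
      "code": 2,
      "name": "medications",
      "keywords": [
        "medication", "medications", "humira", "remicade", "infliximab",
        "adalimumab", "prednisone", "mesalamine", "azathioprine", "tylenol",
        "dose", "refill", "prescription", "pharmacy"
      ]
    },
    {
      "code": 3,
      "name": "appointments",
      "keywords": [
        "appointment", "appointments", "schedule", "reschedule", "cancel",
        "visit", "clinic", "follow up", "booking"
      ]
    },
    {
      "code": 4,
      "name": "laboratory investigations",
      "keywords": [
        "lab", "labs", "bloodwork", "blood test", "lab results",
        "calprotectin", "crp", "quest"
      ]
    },
    {
      "code": 5,
      "name": "finance/insurance",
      "keywords": [
        "insurance", "bill", "billing", "copay", "cost", "coverage",
        "claim", "authorization", "payment"
      ]
    },
    {
      "code": 6,
      "name": "communications",
      "keywords": [
        "message", "call", "email", "contact", "reach", "question",
        "update", "phone call", "fax"
      ]
    },
    {
      "code": 7,
      "name": "procedures",
      "keywords": [
        "colonoscopy", "endoscopy", "procedure", "scope", "biopsy",
        "surgery", "infusion", "ct scan", "mri"
      ]
    },
    {
      "code": 8,
      "name": "miscellaneous",
      "fallback": true,
      "keywords": []
    }
  ]
}
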