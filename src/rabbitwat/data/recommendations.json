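{
  "physical": [
    "Develop training on signs of pain in rabbits for personnel working with rabbits.",
    "Review policies on pain management to ensure in line with current veterinary recommendations for rabbits."
  ],
  "behavioral": [
    "Implement regular, proactive behavioral assessments for rabbits.",
    "Introduce more social housing for rabbits, or look for opportunities for protected social contact for animals that cannot be socially housed."
  ],
  "environmental": [
    "Provide more visual barriers in housing for rabbits to get away from humans and conspecifics.",
    "Provide thermoneutral surfaces for rabbits to rest on.",
    "Provide substrate within home enclosure.",
    "If housing does not provide opportunities for natural behaviors and postures, provide exercise opportunities outside of home enclosure.",
    "Develop formalized behavioral management program for rabbits.",
    "Implement a rotating resource schedule.",
    "Provide foraging and chewing opportunities and monitor animals to ensure resources are being used as intended."
  ],
  "training": [
    "Develop programs for personnel on how to habituate and train rabbits, and how to build positive relationships.",
    "Formalize habituation and training programs, implementing more habituation to procedures and positive reinforcement training to encourage cooperation.",
    "Document animals not responding well and needing additional attention."
  ],
  "procedural": [
    "Provide rewards after procedures.",
    "Develop policy on cumulative use and humane endpoints.",
    "Use catheters for procedures that require repeat blood collections.",
    "Evaluate scheduling practices to reduce personnel feeling rushed."
  ],
  "culture_of_care": [
    "Implement formal program on compassion fatigue and resiliency building and/or raise awareness of existing resources.",
    "Implement and communicate protocol for allowing personnel to opt out of practices when uncomfortable or overwhelmed.",
    "Provide personnel a quiet place."
  ]
}
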