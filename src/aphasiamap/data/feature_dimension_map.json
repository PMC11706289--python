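{
  "description": "Packaged feature-to-dimension scoring map for the 23 connected-speech rating features that enter the four dimension scores. Reconstructed from the published per-dimension feature counts (Paraphasia 9, Logopenia 8, Agrammatism 7, Motor speech 5; 29 feature-dimension pairs over 23 unique features) with assignments informed by the rating system's feature definitions; supply your own map file to override. sign = -1 marks a reverse-scored feature (rating is mirrored before rescaling).",
  "entries": [
    {"feature": "Phonemic paraphasia", "dimension": "Paraphasia", "sign": 1},
    {"feature": "Semantic paraphasia", "dimension": "Paraphasia", "sign": 1},
    {"feature": "Neologism", "dimension": "Paraphasia", "sign": 1},
    {"feature": "Jargon", "dimension": "Paraphasia", "sign": 1},
    {"feature": "Paragrammatism", "dimension": "Paraphasia", "sign": 1},
    {"feature": "Retracing", "dimension": "Paraphasia", "sign": 1},
    {"feature": "False starts", "dimension": "Paraphasia", "sign": 1},
    {"feature": "Conduite d'approche", "dimension": "Paraphasia", "sign": 1},
    {"feature": "Empty speech", "dimension": "Paraphasia", "sign": 1},
    {"feature": "Anomia", "dimension": "Logopenia", "sign": 1},
    {"feature": "Abandoned utterances", "dimension": "Logopenia", "sign": 1},
    {"feature": "Empty speech", "dimension": "Logopenia", "sign": 1},
    {"feature": "Pauses between utterances", "dimension": "Logopenia", "sign": 1},
    {"feature": "Pauses within utterances", "dimension": "Logopenia", "sign": 1},
    {"feature": "Halting and effortful", "dimension": "Logopenia", "sign": 1},
    {"feature": "Reduced speech rate", "dimension": "Logopenia", "sign": 1},
    {"feature": "Short and simplified utterances", "dimension": "Logopenia", "sign": 1},
    {"feature": "Omission of bound morphemes", "dimension": "Agrammatism", "sign": 1},
    {"feature": "Omission of function words", "dimension": "Agrammatism", "sign": 1},
    {"feature": "Short and simplified utterances", "dimension": "Agrammatism", "sign": 1},
    {"feature": "Stereotypies and automatisms", "dimension": "Agrammatism", "sign": 1},
    {"feature": "Perseveration", "dimension": "Agrammatism", "sign": 1},
    {"feature": "Reduced speech rate", "dimension": "Agrammatism", "sign": 1},
    {"feature": "Paragrammatism", "dimension": "Agrammatism", "sign": -1},
    {"feature": "Apraxia of speech", "dimension": "Motor speech", "sign": 1},
    {"feature": "Dysarthria", "dimension": "Motor speech", "sign": 1},
    {"feature": "Distorted articulation", "dimension": "Motor speech", "sign": 1},
    {"feature": "Halting and effortful", "dimension": "Motor speech", "sign": 1},
    {"feature": "Reduced speech rate", "dimension": "Motor speech", "sign": 1}
  ]
}
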