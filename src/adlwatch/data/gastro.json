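{
  "disease": "gastrointestinal",
  "variables": [
    {
      "label": "leaving_home",
      "aspect": "duration",
      "normal_min": 9000,
      "normal_max": 14400,
      "corners": {
        "Abnormal-": [null, null, 400, 6400],
        "Normal": [4000, 10000, 13050, 15750],
        "Abnormal+": [13050, 15750, null, null]
      }
    },
    {
      "label": "leaving_home",
      "aspect": "frequency",
      "normal_min": 1,
      "normal_max": 2
    },
    {
      "label": "going_to_toilet",
      "aspect": "duration",
      "normal_min": 2200,
      "normal_max": 3600
    },
    {
      "label": "going_to_toilet",
      "aspect": "frequency",
      "normal_min": 10,
      "normal_max": 12
    },
    {
      "label": "eating",
      "aspect": "duration",
      "normal_min": 2880,
      "normal_max": 4500
    },
    {
      "label": "eating",
      "aspect": "frequency",
      "normal_min": 3,
      "normal_max": 4
    },
    {
      "label": "sleeping",
      "aspect": "duration",
      "normal_min": 31200,
      "normal_max": 40800,
      "corners": {
        "Abnormal-": [null, null, 22000, 32000],
        "Normal": [27000, 32000, 38400, 43200],
        "Abnormal+": [38400, 43200, null, null]
      }
    },
    {
      "label": "sleeping",
      "aspect": "frequency",
      "normal_min": 1,
      "normal_max": 2
    }
  ],
  "rules": [
    {
      "connective": "AND",
      "clauses": [
        [["eating", "duration", "Normal"]],
        [["eating", "frequency", "Normal"]],
        [["sleeping", "duration", "Normal"]],
        [["sleeping", "frequency", "Normal"]],
        [["leaving_home", "duration", "Normal"]],
        [["leaving_home", "frequency", "Normal"]],
        [["going_to_toilet", "duration", "Normal"]],
        [["going_to_toilet", "frequency", "Normal"]]
      ],
      "consequent": "Low"
    },
    {
      "connective": "AND",
      "clauses": [
        [["eating", "frequency", "Abnormal-"]],
        [["leaving_home", "frequency", "Abnormal-"]],
        [["sleeping", "duration", "Abnormal-"]]
      ],
      "consequent": "High"
    },
    {
      "connective": "AND",
      "clauses": [
        [["eating", "frequency", "Abnormal-"], ["eating", "duration", "Abnormal-"]],
        [["leaving_home", "frequency", "Abnormal-"], ["leaving_home", "duration", "Abnormal-"]],
        [["going_to_toilet", "duration", "Abnormal+"], ["going_to_toilet", "frequency", "Abnormal+"]],
        [["sleeping", "duration", "Abnormal-"], ["sleeping", "frequency", "Abnormal-"]]
      ],
      "consequent": "Very high"
    }
  ],
  "output_sets": {
    "Low": [0.0, 0.0, 0.2, 0.4],
    "High": [0.2, 0.4, 0.6, 0.8],
    "Very high": [0.6, 0.8, 1.0, 1.0]
  },
  "cutpoints": [0.3333333333333333, 0.6666666666666666],
  "alerts": {"Low": "Minor", "High": "Important", "Very high": "Major"},
  "generate_count_rules": true,
  "grid_n": 1001
}
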