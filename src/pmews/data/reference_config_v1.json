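{
  "prevalence": 0.684,
  "mu1": 1.89,
  "sigma1": 2.3,
  "physio": {
    "respiratory_rate": {
      "slope": 0.2838716402439338,
      "cutpoints": [
        1.4928173841637857,
        5.525291134606697,
        7.2412374113909115
      ]
    },
    "spo2": {
      "slope": 1.561294021341636,
      "cutpoints": [
        4.739256629078316,
        6.249289352648428,
        7.759322076218537
      ]
    },
    "heart_rate": {
      "slope": 0.2838716402439338,
      "cutpoints": [
        1.407020070324575,
        5.353696506928274,
        7.069642783712491
      ]
    },
    "systolic_bp": {
      "slope": 0.2838716402439338,
      "cutpoints": [
        1.6644120118422077,
        5.439493820767485,
        7.412832039069334
      ]
    },
    "temperature": {
      "slope": 1.561294021341636,
      "cutpoints": [
        4.4647052247928425,
        6.3865650547911645
      ]
    },
    "consciousness": {
      "slope": 1.561294021341636,
      "cutpoints": [
        5.356997288720636,
        6.798392161219377,
        8.10251133157538
      ]
    }
  },
  "social_flags": {
    "age_over_65": {
      "intercept": -2.8971798899570405,
      "slope": 0.5
    },
    "socially_isolated": {
      "intercept": -3.6,
      "slope": 0.55
    },
    "chronic_disease": {
      "intercept": -3.0,
      "slope": 0.6
    }
  },
  "performance_status": {
    "slope": 1.002284873809299,
    "cutpoints": [
      4.149867598752394,
      5.149867598752393,
      6.149867598752393,
      7.149867598752393
    ]
  },
  "age": {
    "mu_under": 46.639450869104564,
    "sd_under": 16.0,
    "mu_over": 71680.81293848978,
    "sd_over": 7.0,
    "min_age": 12.0,
    "max_age": 100.0
  },
  "mu0": 0.0,
  "sigma0": 1.0,
  "high_side_prob": {
    "respiratory_rate": 0.8,
    "heart_rate": 0.75,
    "temperature": 0.7
  },
  "caps": {
    "respiratory_rate": [
      2,
      60
    ],
    "spo2": [
      60,
      100
    ],
    "heart_rate": [
      20,
      200
    ],
    "systolic_bp": [
      40,
      250
    ],
    "temperature": [
      30.0,
      42.0
    ]
  },
  "seed": 0
}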