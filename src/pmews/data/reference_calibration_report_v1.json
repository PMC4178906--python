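{
  "entries": [
    {
      "name": "prevalence",
      "target": 0.684,
      "achieved": 0.6861125,
      "rel_dev": 0.0030884502923976044,
      "weight": 1.0
    },
    {
      "name": "pmews_mean",
      "target": 2.71,
      "achieved": 2.707825,
      "rel_dev": -0.0008025830258301904,
      "weight": 1.0
    },
    {
      "name": "pmews_sd",
      "target": 3.55,
      "achieved": 3.6776212096425933,
      "rel_dev": 0.03594963651904042,
      "weight": 1.0
    },
    {
      "name": "physio_mean",
      "target": 1.97,
      "achieved": 2.0073875,
      "rel_dev": 0.018978426395939153,
      "weight": 1.0
    },
    {
      "name": "physio_sd",
      "target": 2.86,
      "achieved": 2.663289432210302,
      "rel_dev": -0.06877991880758667,
      "weight": 1.0
    },
    {
      "name": "social_mean",
      "target": 0.75,
      "achieved": 0.7004374999999999,
      "rel_dev": -0.06608333333333342,
      "weight": 1.0
    },
    {
      "name": "social_sd",
      "target": 1.16,
      "achieved": 1.2971810669347255,
      "rel_dev": 0.1182595404609703,
      "weight": 1.0
    },
    {
      "name": "age_mean",
      "target": 50.58,
      "achieved": 51.03677999999999,
      "rel_dev": 0.009030842230130384,
      "weight": 1.0
    },
    {
      "name": "age_sd",
      "target": 22.15,
      "achieved": 22.450855910895907,
      "rel_dev": 0.013582659634126788,
      "weight": 1.0
    },
    {
      "name": "frac_age_over_65",
      "target": 0.322,
      "achieved": 0.13453749999999998,
      "rel_dev": -0.5821816770186337,
      "weight": 1.0
    },
    {
      "name": "frac_isolated",
      "target": 0.143,
      "achieved": 0.0882625,
      "rel_dev": -0.3827797202797203,
      "weight": 1.0
    },
    {
      "name": "frac_chronic",
      "target": 0.525,
      "achieved": 0.15281250000000002,
      "rel_dev": -0.7089285714285714,
      "weight": 1.0
    },
    {
      "name": "ppv_at_cutoff4",
      "target": 0.976,
      "achieved": 0.9752221905247593,
      "rel_dev": -0.0007969359377465602,
      "weight": 1.0
    },
    {
      "name": "auroc_total",
      "target": 0.738,
      "achieved": 0.722122293259825,
      "rel_dev": -0.021514507778014863,
      "weight": 1.0
    },
    {
      "name": "auroc_physio",
      "target": 0.692,
      "achieved": 0.7089852165933335,
      "rel_dev": 0.024545110684007977,
      "weight": 1.0
    },
    {
      "name": "auroc_social",
      "target": 0.667,
      "achieved": 0.6543981136558348,
      "rel_dev": -0.018893382824835468,
      "weight": 1.0
    }
  ],
  "objective_initial": 0.03106374135550266,
  "objective_final": 0.029010078233750812,
  "iterations": 117,
  "n_evaluations": 370,
  "n_per_eval": 20000,
  "replicates": 4,
  "seeds": [
    201,
    202,
    203,
    204
  ],
  "notes": "Staged Nelder-Mead calibration with common random numbers (n_per_eval=20000, 2 replicates per stage, chained restarts). Objective weights: flag marginals (age>65, isolation, chronic) 0.0 because they are jointly unsatisfiable with the printed social-score mean (0.322+0.143+0.525=0.99>0.75); ppv_at_cutoff4 3.0 and the three AUROCs 2.0 as primary operating characteristics; all other constraints 1.0. In the final stages the latent class separation (mu1=1.89, sigma1=2.30; pair-ranking ceiling 0.775) and the isolation/chronic/age-slope flag links were held fixed. Achieved values in this report are a fresh evaluation of the frozen config (seeds 201-204). This configuration is one member of the family of generators consistent with the printed summary constraints, not a reconstruction of the study's unpublished patient-level data."
}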