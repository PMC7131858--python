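{
  "description": "Published stage counts from the first five years (January 2012 - December 2016) of the Emilia-Romagna regional hereditary breast/ovarian cancer screening programme. Counts are keyed in from the programme's published report tables and serve as funnel-reporting inputs; they are not outputs of this package.",
  "stages": [
    ["rbcsp_screened", 660040],
    ["questionnaire_answered", 659747],
    ["questionnaire_refused", 293],
    ["spoke_invited_rbcsp", 22289],
    ["spoke_attended_rbcsp", 5615],
    ["spoke_referred_gp", 2258],
    ["spoke_referred_specialist", 3794],
    ["spoke_arrived", 11667],
    ["spoke_refused_assessment", 330],
    ["spoke_evaluated", 11337],
    ["profile_LR", 3600],
    ["profile_IR", 3110],
    ["profile_HR", 4627],
    ["profile_LR_IR", 6710],
    ["hub_accepted_from_HR", 2815],
    ["hub_direct", 2739],
    ["hub_evaluated", 5554],
    ["tested", 2342],
    ["test_criteria_not_met", 3212],
    ["carriers", 544]
  ],
  "derived": [
    ["spoke attendance among RBCSP-invited", "spoke_attended_rbcsp", "spoke_invited_rbcsp"],
    ["specialist share of Spoke arrivals", "spoke_referred_specialist", "spoke_arrived"],
    ["high-risk fraction among evaluated", "profile_HR", "spoke_evaluated"],
    ["low/intermediate fraction among evaluated", "profile_LR_IR", "spoke_evaluated"],
    ["Hub acceptance among high-risk", "hub_accepted_from_HR", "profile_HR"],
    ["test rate among Hub-evaluated", "tested", "hub_evaluated"],
    ["carrier yield among tested", "carriers", "tested"]
  ],
  "invited_by_age": {
    "columns": ["age", "invited"],
    "rows": [
      ["45-49", 8518],
      ["50-54", 3836],
      ["55-59", 2856],
      ["60-64", 2511],
      ["65-69", 2354],
      ["70-74", 2214]
    ],
    "total": 22289
  },
  "spoke_arrivals_by_age_source": {
    "columns": ["age", "gp", "specialist", "rbcsp", "total", "refuse", "LR", "IR", "HR"],
    "rows": [
      ["<35", 560, 840, 0, 1400, 32, 237, 424, 707],
      ["35-39", 403, 722, 0, 1125, 26, 191, 365, 543],
      ["40-44", 509, 887, 49, 1445, 35, 309, 453, 648],
      ["45-49", 246, 432, 1832, 2510, 96, 835, 663, 916],
      ["50-54", 214, 369, 1153, 1736, 48, 612, 423, 653],
      ["55-59", 140, 234, 861, 1235, 28, 458, 260, 489],
      ["60-64", 100, 146, 743, 989, 26, 409, 234, 320],
      ["65-69", 65, 102, 599, 766, 30, 339, 180, 217],
      ["70-74", 21, 62, 378, 461, 9, 210, 108, 134]
    ],
    "totals": ["Total", 2258, 3794, 5615, 11667, 330, 3600, 3110, 4627]
  },
  "hub_referral_by_source": {
    "columns": ["source", "under35", "under35_hub", "35_44", "35_44_hub", "45_74", "45_74_hub", "total", "total_hub"],
    "rows": [
      ["gp", 556, 289, 909, 473, 776, 443, 2241, 1205],
      ["specialist", 812, 418, 1552, 699, 1320, 651, 3684, 1768],
      ["rbcsp", 0, 0, 48, 19, 5364, 1635, 5412, 1654]
    ],
    "totals": ["Total", 1368, 717, 2509, 1191, 7460, 2729, 11337, 4627]
  },
  "tested_by_age": {
    "columns": ["age", "LR", "IR", "HR", "carriers", "total"],
    "rows": [
      ["<25", 44, 23, 8, 36, 111],
      ["25-29", 23, 19, 24, 35, 101],
      ["30-34", 44, 24, 58, 49, 175],
      ["35-39", 68, 38, 115, 62, 283],
      ["40-44", 64, 44, 115, 80, 303],
      ["45-49", 83, 45, 123, 66, 317],
      ["50-54", 74, 24, 132, 58, 288],
      ["55-59", 57, 15, 107, 38, 217],
      ["60-64", 41, 14, 92, 37, 184],
      ["65-69", 40, 3, 82, 35, 160],
      ["70-74", 51, 3, 101, 48, 203]
    ],
    "totals": ["Total", 589, 252, 957, 544, 2342]
  }
}
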