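# Bundled summary tables from a two-experiment recognition-memory study of
# false-memory rejection (Experiment 1: concrete words in coloured fonts;
# Experiment 2: door-scene photographs).  Encoding orientation (colour naming
# vs. category naming) was manipulated between subjects; test lists mixed
# targets with category lures, colour lures, and critical lures, rated on a
# 4-point confidence scale (1 = definitely new ... 4 = definitely old).
#
# "proportions" are participant-mean response proportions per rating level;
# with equal trials per participant they equal pooled proportions, so pooled
# integer counts are exactly recoverable (see recmodels.design).
# "reference" holds the published model-based estimates used by the
# reproduction report for comparison.

designs:
  exp1:
    label: exp1
    materials: words
    n_participants: {colour: 27, category: 26}
    trials_per_item_class: {target: 27, category_lure: 9, colour_lure: 9, critical_lure: 9}
  exp2:
    label: exp2
    materials: pictures
    n_participants: {colour: 35, category: 36}
    trials_per_item_class: {target: 18, category_lure: 6, colour_lure: 6, critical_lure: 9}

proportions:
  - {experiment: exp1, condition: colour, item_class: target,        p: [0.089, 0.165, 0.199, 0.547], mean_rating: 3.204}
  - {experiment: exp1, condition: colour, item_class: category_lure, p: [0.568, 0.309, 0.074, 0.049], mean_rating: 1.605}
  - {experiment: exp1, condition: colour, item_class: colour_lure,   p: [0.436, 0.370, 0.123, 0.070], mean_rating: 1.827}
  - {experiment: exp1, condition: colour, item_class: critical_lure, p: [0.362, 0.391, 0.140, 0.107], mean_rating: 1.992}
  - {experiment: exp1, condition: category, item_class: target,        p: [0.044, 0.105, 0.181, 0.669], mean_rating: 3.476}
  - {experiment: exp1, condition: category, item_class: category_lure, p: [0.547, 0.316, 0.103, 0.034], mean_rating: 1.624}
  - {experiment: exp1, condition: category, item_class: colour_lure,   p: [0.859, 0.098, 0.021, 0.021], mean_rating: 1.205}
  - {experiment: exp1, condition: category, item_class: critical_lure, p: [0.393, 0.325, 0.162, 0.120], mean_rating: 2.008}
  - {experiment: exp2, condition: colour, item_class: target,        p: [0.059, 0.105, 0.214, 0.622], mean_rating: 3.400}
  - {experiment: exp2, condition: colour, item_class: category_lure, p: [0.857, 0.062, 0.052, 0.029], mean_rating: 1.252}
  - {experiment: exp2, condition: colour, item_class: colour_lure,   p: [0.738, 0.152, 0.081, 0.029], mean_rating: 1.400}
  - {experiment: exp2, condition: colour, item_class: critical_lure, p: [0.270, 0.251, 0.289, 0.190], mean_rating: 2.400}
  - {experiment: exp2, condition: category, item_class: target,        p: [0.063, 0.105, 0.148, 0.684], mean_rating: 3.452}
  - {experiment: exp2, condition: category, item_class: category_lure, p: [0.602, 0.222, 0.097, 0.079], mean_rating: 1.653}
  - {experiment: exp2, condition: category, item_class: colour_lure,   p: [0.755, 0.120, 0.069, 0.056], mean_rating: 1.426}
  - {experiment: exp2, condition: category, item_class: critical_lure, p: [0.321, 0.278, 0.219, 0.182], mean_rating: 2.262}

reference:
  g2:
    exp1: {value: 5.22, df: 5}
    exp2: {value: 3.974, df: 5}
    combined: {value: 9.19, df: 10}
  delta_g2:
    exp1:
      Do_condition: 24.31
      Dn_col_condition: 27.77
      n_col_condition: 3.63
      category_Dn_col_vs_Dn_cat: 13.26
      colour_Dn_cat_vs_Dn_col: 4.49
      colour_Dn_crit_vs_Dn_col: 2.03
    exp2:
      Do_condition: 0.05
      s_condition: 4.33
      Dn_cat_condition: 8.75
      Dn_crit_condition: 3.96
      n_cat_condition: 9.49
    interaction:
      Dn_col: 13.12
      Dn_cat: 0.90
      Do: 4.84
  uvsdt:  # pooled-data fits, one per (experiment, condition, lure type); (SE)
    exp1:
      colour:
        category_lure: {d_a: 1.667, se_d_a: 0.0864, x_c: 1.086, se_x_c: 0.0920}
        colour_lure:   {d_a: 1.422, se_d_a: 0.0811, x_c: 0.818, se_x_c: 0.0833}
        critical_lure: {d_a: 1.250, se_d_a: 0.0800, x_c: 0.621, se_x_c: 0.0791}
      category:
        category_lure: {d_a: 2.063, se_d_a: 0.0921, x_c: 1.067, se_x_c: 0.0933}
        colour_lure:   {d_a: 2.716, se_d_a: 0.1314, x_c: 1.640, se_x_c: 0.1258}
        critical_lure: {d_a: 1.591, se_d_a: 0.0904, x_c: 0.542, se_x_c: 0.0795}
    exp2:
      colour:
        category_lure: {d_a: 2.461, se_d_a: 0.1427, x_c: 1.435, se_x_c: 0.1149}
        colour_lure:   {d_a: 2.207, se_d_a: 0.1093, x_c: 1.228, se_x_c: 0.1035}
        critical_lure: {d_a: 1.127, se_d_a: 0.0795, x_c: 0.062, se_x_c: 0.0658}
      category:
        category_lure: {d_a: 1.860, se_d_a: 0.0981, x_c: 0.908, se_x_c: 0.0910}
        colour_lure:   {d_a: 2.140, se_d_a: 0.1145, x_c: 1.165, se_x_c: 0.1001}
        critical_lure: {d_a: 1.311, se_d_a: 0.0790, x_c: 0.259, se_x_c: 0.0659}
  wald_z:
    exp1:
      d_a_category_lure: 3.14
      d_a_colour_lure: 8.38
      d_a_critical_lure: 2.82
      x_c_colour_lure: 5.45
    exp2:
      d_a_category_lure: 3.47
      x_c_category_lure: 3.60
      x_c_critical_lure: 2.11
  descriptives:
    exp1_colour_target_mean_rating: 3.204
    exp2_critical_lure_false_alarm_rate: 0.44
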