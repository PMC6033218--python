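{
 "provenance": "SSIGN point assignments following the original Mayo Clinic outcome algorithm (Frank et al., J Urol 2002), as applied in subsequent external validations. Editable config: review against the primary reference before clinical use. Risk-stratum bins are a common grouping and are configurable.",
 "t_points": {"1": 0, "2": 1, "3": 2, "3A": 2, "3B": 2, "3C": 2, "4": 2},
 "n_points": {"0": 0, "1": 2, "2": 2},
 "m_points": {"0": 0, "1": 4},
 "grade_points": {"1": 0, "2": 0, "3": 1, "4": 3},
 "necrosis_points": {"absent": 0, "present": 2},
 "size_threshold_cm": 10.0,
 "size_points_below": 0,
 "size_points_at_or_above": 2,
 "bins": {"low": [0, 2], "intermediate": [3, 4], "high": [5, 15]}
}
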