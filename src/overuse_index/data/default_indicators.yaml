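# Default overuse-indicator definitions (17 indicators).
#
# These are illustrative, self-consistent definitions named after widely
# recognized low-value services.  The code sets are compact ICD-10-style
# prefixes chosen to be mutually disjoint so that synthetic claims round-trip
# exactly; they are NOT validated clinical code lists and must be replaced
# with curated lists before any use on real claims.
#
# Fields per indicator: indicator_id, name, optional min_age/max_age/sex,
# eligibility_dx_codes / eligibility_px_codes (both absent => demographic-only
# eligibility with event-claim attribution), event_codes, attribution,
# eligibility_window_days, prefix_match.

indicators:
  - indicator_id: 1
    name: "Brain MRI for uncomplicated headache"
    min_age: 66
    eligibility_dx_codes: [R51]
    event_codes: [B030]
    attribution: eligibility_claim
    eligibility_window_days: 30
  - indicator_id: 2
    name: "Head CT for simple syncope"
    min_age: 66
    eligibility_dx_codes: [R55]
    event_codes: [B020]
    attribution: eligibility_claim
    eligibility_window_days: 30
  - indicator_id: 3
    name: "Carotid ultrasound for dizziness"
    min_age: 66
    eligibility_dx_codes: [R42]
    event_codes: [B34D]
    attribution: eligibility_claim
    eligibility_window_days: 30
  - indicator_id: 4
    name: "EEG for headache"
    min_age: 66
    eligibility_dx_codes: [G44]
    event_codes: [4A00]
    attribution: eligibility_claim
    eligibility_window_days: 60
  - indicator_id: 5
    name: "Spine imaging for uncomplicated low back pain"
    min_age: 66
    eligibility_dx_codes: [M545]
    event_codes: [BR39]
    attribution: eligibility_claim
    eligibility_window_days: 42
  - indicator_id: 6
    name: "Spinal injection for low back pain"
    min_age: 66
    eligibility_dx_codes: [M544]
    event_codes: [0SH3]
    attribution: eligibility_claim
    eligibility_window_days: 84
  - indicator_id: 7
    name: "Vertebroplasty for osteoporotic fracture"
    min_age: 66
    eligibility_dx_codes: [M80]
    event_codes: [0PS3]
    attribution: eligibility_claim
    eligibility_window_days: 84
  - indicator_id: 8
    name: "Knee arthroscopy for osteoarthritis"
    min_age: 66
    eligibility_dx_codes: [M17]
    event_codes: [0SJC]
    attribution: eligibility_claim
    eligibility_window_days: 84
  - indicator_id: 9
    name: "Renal artery revascularization for renovascular disease"
    min_age: 66
    eligibility_dx_codes: [I701]
    event_codes: ["0470"]
    attribution: eligibility_claim
    eligibility_window_days: 84
  - indicator_id: 10
    name: "Carotid endarterectomy in asymptomatic stenosis"
    min_age: 66
    eligibility_dx_codes: [I652]
    event_codes: [03CH]
    attribution: eligibility_claim
    eligibility_window_days: 84
  - indicator_id: 11
    name: "Inferior vena cava filter placement"
    min_age: 66
    eligibility_dx_codes: [I82]
    event_codes: [06H0]
    attribution: eligibility_claim
    eligibility_window_days: 30
  - indicator_id: 12
    name: "Cervical cancer screening in women over 85"
    min_age: 85
    sex: F
    event_codes: [0UDB]
    attribution: event_claim
    eligibility_window_days: 84
  - indicator_id: 13
    name: "Hysterectomy for benign uterine disease"
    min_age: 66
    sex: F
    eligibility_dx_codes: [N920]
    event_codes: [0UT9]
    attribution: eligibility_claim
    eligibility_window_days: 84
  - indicator_id: 14
    name: "Arthroscopic shoulder debridement for impingement"
    min_age: 66
    eligibility_dx_codes: [M751]
    event_codes: [0RJK]
    attribution: eligibility_claim
    eligibility_window_days: 84
  - indicator_id: 15
    name: "Cardiac stress testing before low-risk surgery"
    min_age: 66
    eligibility_dx_codes: [Z0181]
    eligibility_px_codes: ["00160"]
    event_codes: [B240]
    attribution: eligibility_claim
    eligibility_window_days: 30
  - indicator_id: 16
    name: "Chest CT for uncomplicated acute bronchitis"
    min_age: 66
    eligibility_dx_codes: [J20]
    event_codes: [BW24]
    attribution: eligibility_claim
    eligibility_window_days: 30
  - indicator_id: 17
    name: "Prostate biopsy in men over 85"
    min_age: 85
    sex: M
    event_codes: [0VB0]
    attribution: event_claim
    eligibility_window_days: 84
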