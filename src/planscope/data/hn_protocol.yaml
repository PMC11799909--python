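# Organ-at-risk dose-constraint protocol for head-and-neck VMAT plans
# (RTOG 0225 / 0615 style).  All comparisons are strict (<); limits in Gy.
# "alternate" is an 'or' clause; paired_alternate means the alternate is
# satisfied when at least one side of a left/right organ pair meets it.
rules:
  - structure: "Brain stem"
    statistic: Dmax
    limit: 54
    alternate: {statistic: "D1%", limit: 60}
  - structure: "Chiasm"
    statistic: Dmax
    limit: 54
    alternate: {statistic: "D1%", limit: 60}
  - structure: "Cochlea"
    statistic: Dmean
    limit: 45
  - structure: "IAC"
    statistic: Dmean
    limit: 45
  - structure: "Eye"
    statistic: Dmean
    limit: 35
  - structure: "Lens"
    statistic: Dmax
    limit: 15
  - structure: "Optic nerve"
    statistic: Dmax
    limit: 54
    alternate: {statistic: "D1%", limit: 60}
  - structure: "Parotid"
    statistic: Dmean
    limit: 26
    alternate: {statistic: Dmean, limit: 30}
    paired_alternate: true
  - structure: "Spinal cord"
    statistic: Dmax
    limit: 45
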