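"""Split a tiny recurrent-event cohort into piece-wise exponential data.

Three hand-written subjects; cutpoints are the unique episode times. Each
printed row is one subject x interval pseudo-observation: `exposure` is the
exact days at risk in that interval (its log is the Poisson offset) and
`event` marks the interval where an episode ended.
"""

import pammkit as pk

histories = [
    pk.SubjectHistory("child-1", 0, 728, [100.0, 250.0], {"male": 1}),
    pk.SubjectHistory("child-2", 0, 300, [], {"male": 0}),          # censored at day 300
    pk.SubjectHistory("child-3", 0, 728, [45.0], {"male": 0}),
]

window = pk.StudyWindow()  # (0, 728], 14-day episode gap
grid = pk.build_cutpoints(histories, window)
print("cutpoints:", grid.cutpoints.tolist())

ped = pk.split_to_ped(histories, grid, window)
print(ped.to_string(index=False))

check = ped.groupby("id")[["exposure", "event"]].sum()
print("\nper-subject totals (exposure must equal follow-up, events must equal episodes):")
print(check)
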