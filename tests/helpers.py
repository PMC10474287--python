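"""Small shared helpers for the test suite."""


def cohort_groups(truth):
    """Sample IDs per true status label."""
    by = {"control": [], "case_initial": [], "candidate": [], "independent_control": []}
    for sid, st in truth.status.items():
        by[st].append(sid)
    return by
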