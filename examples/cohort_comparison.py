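"""Compare a healthy and a patient synthetic cohort on trajectory deviation.

Simulates 15 healthy-profile and 7 patient-profile subjects (two trials
each, averaged), then contrasts the XCoB distributions with the exact
Mann-Whitney U test.  Patients sway more, so their mean XCoB should be
clearly higher and the test clearly significant.
"""

import dataclasses

import vestigait as vg


def xcob_of(cfg):
    a, _ = vg.simulate_trial(cfg)
    b, _ = vg.simulate_trial(dataclasses.replace(cfg, seed=cfg.seed + 1))
    return vg.analyze_subject([a, b]).trajectory.xcob_pct


healthy = [xcob_of(c) for c in vg.sample_cohort("healthy", 15, seed=1)]
patients = [xcob_of(c) for c in vg.sample_cohort("patient", 7, seed=2)]

comp = vg.compare_groups(healthy, patients, metric="xcob_pct")
a, b = comp.group_a, comp.group_b
print(f"healthy  (n={a.n}): XCoB {a.mean:5.2f} +- {a.sd:.2f} %, "
      f"median {a.median:.2f} (IQR {a.iqr_low:.2f}-{a.iqr_high:.2f})")
print(f"patients (n={b.n}): XCoB {b.mean:5.2f} +- {b.sd:.2f} %, "
      f"median {b.median:.2f} (IQR {b.iqr_low:.2f}-{b.iqr_high:.2f})")
print(f"Mann-Whitney U = {comp.u:g}, Z = {comp.z:.3f}, p = {comp.p:.5f} ({comp.method})")
print()
print("A larger XCoB means a larger average deviation from the straight")
print("walking line; U is the smaller one-sided statistic, p is two-sided.")
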