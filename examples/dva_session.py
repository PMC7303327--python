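"""Run a static acuity baseline and a standing dynamic acuity session.

A simulated observer with 0.0 logMAR static acuity and a 0.2 logMAR dynamic
penalty reads tumbling-E optotypes; presentations in the dynamic session
are gated on the 2 Hz head yaw exceeding 120 deg/s rightward.  Prints the
two thresholds and the resulting decrement with its abnormality flag.
"""

import vestigait as vg
from vestigait.io import to_yaw_series

chart = vg.build_chart()
observer = vg.make_observer(static_threshold_logmar=0.0, dynamic_penalty_logmar=0.2,
                            guess_rate=0.25, lapse_rate=0.02, seed=7)

sva = vg.run_session("SVA", chart, observer, rng_seed=7)
sva_smallest = max(p.level_index for p in sva.presentations if p.correct)
print(f"SVA: {len(sva.presentations)} presentations, threshold "
      f"{sva.threshold_logmar:.2f} logMAR ({sva.termination})")

trial, _ = vg.simulate_trial(vg.SynthConfig(seed=7, noise_sd_deg=0.0))
head = to_yaw_series(trial.head, "head")
dyn = vg.run_session("sDVA_right", chart, observer, head_yaw=head,
                     sva_smallest_level=sva_smallest, rng_seed=8)
print(f"sDVA_right: start level {dyn.start_level} (4 sizes above the SVA result), "
      f"{len(dyn.presentations)} presentations, threshold "
      f"{dyn.threshold_logmar:.2f} logMAR ({dyn.termination})")

result = vg.dva_decrement(sva.threshold_logmar, dyn.threshold_logmar, mode="sDVA_right")
print(f"decrement: {result.decrement_logmar:.2f} logMAR -> "
      f"{'ABNORMAL' if result.abnormal else 'normal'} "
      f"(abnormal means a loss strictly greater than 0.2 logMAR with head motion)")
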