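"""Recompute the published group aggregates from the bundled tables.

The package ships the proof-of-concept study's printed per-participant
tables (completed sessions, success rates, pre/post AHI).  This script
reproduces the group numbers from them.
"""

from myotrain import TaskKind, compliance_from_counts, paired_permutation_test
from myotrain.analytics import round_half_up, success_summary_from_scores
from myotrain.clinical_tables import load_ahi_pre_post, load_success_rates, session_counts

comp = compliance_from_counts(session_counts())
print(f"overall compliance: {comp.overall_completed}/{comp.overall_prescribed}"
      f" = {comp.overall_pct}% (worst participant {round_half_up(100 * comp.min_fraction):.0f}%)")

rates = load_success_rates()
for kind, pre, post in ((TaskKind.TONGUE, "tongue_baseline", "tongue_post"),
                        (TaskKind.LIP, "lip_baseline", "lip_post")):
    s = success_summary_from_scores(rates[pre], rates[post], kind)
    print(f"{kind.value} success: {s.first_pct}% (SD {s.first_sd:.0f}) -> {s.last_pct}% (SD {s.last_sd:.0f})")

ahi = load_ahi_pre_post()
p = paired_permutation_test(ahi["ahi_pre"], ahi["ahi_post"])
print(f"AHI: {round_half_up(ahi['ahi_pre'].mean(), 1)} -> {round_half_up(ahi['ahi_post'].mean(), 1)}"
      f" events/h (paired sign-flip permutation p = {p:.3f})")
print("The sign-flip p is this package's substitute for the original mixed-model")
print("inference; it is exact over all 2^8 sign assignments of the paired changes.")
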