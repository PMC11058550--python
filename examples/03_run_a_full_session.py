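"""Run one complete simulated training session.

A session is: zero calibration, 2-minute warm-up game (the mouthpiece
warms to thermal steady state), a second zero calibration, maximal-
pressure calibration (tongue then lips), then 4 rounds of breathing, lip
and tongue tasks with a game between rounds - about 35 minutes in total.
"""

from myotrain import build_session_plan, run_session
from myotrain.simulate import SimulatedUser, UserModel

user = SimulatedUser(UserModel(), day=7)  # one week into the programme
record = run_session(user, build_session_plan(seed=1), seed=1)

print(f"completed: {record.completed}, duration: {record.total_duration_s / 60:.1f} min")
for ch, cal in record.max_cals.items():
    print(f"Pmax[{ch.value}] = {cal.pmax:.1f} kPa (rounds used: {cal.rounds_used})")
print("task scores (%):", ", ".join(f"{t.task_kind.value}={t.score_pct:.0f}" for t in record.task_results))
print("game high scores:", ", ".join(f"{g.variant.value}={g.high_score}" for g in record.game_results))
print("Task scores reflect the user's day-7 skill on the learning curve;")
print("game scores are logged for motivation but excluded from success analytics.")
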