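"""The four training games are deterministic, replayable state machines.

Runs the paddle game twice with the same seed and input stream and shows
the trajectories are bit-identical, then lets a ball-tracking controller
rack up bounces (each bounce speeds the ball up by the growth factor).
"""

import numpy as np

from myotrain import GameInput, GameRules, GameVariant, run_game

rules = GameRules(variant=GameVariant.PADDLE)


def wobble(t, state):
    return GameInput(0.04 + 0.03 * np.sin(t), 0.05 + 0.03 * np.cos(1.3 * t))


r1, log1 = run_game(rules, wobble, duration_s=30.0, seed=8, record=True)
r2, log2 = run_game(rules, wobble, duration_s=30.0, seed=8, record=True)
print(f"replay identical: {log1 == log2} (final={r1.final_score}, high={r1.high_score})")


def tracker(t, state):
    # keep both paddles centred on the ball
    frac = np.clip((state.ball_y - rules.paddle_len / 2) / (1 - rules.paddle_len), 0, 1)
    p = frac * rules.pressure_ref_frac
    return GameInput(p, p)


result = run_game(rules, tracker, duration_s=30.0, seed=8)
print(f"tracking controller: {result.final_score} bounces,")
print(f"ball speed grew to {rules.initial_speed * rules.speed_growth**result.final_score:.2f} field/s")
print("Determinism given (rules, controller, seed) is what makes session logs replayable.")
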