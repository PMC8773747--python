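"""Build the two-session stimulus-response schedule and inspect its design.

Each session is 20 trials of a 1 s trial number, five 5 s stimulus-response
repetitions and a 35 s rest; targets are emotional images with an exact
30/70 valence split (positive-minority in session 1, negative-minority in
session 2).
"""

from nirstress import build_session_schedule, trial_onsets

for session in (1, 2):
    sched = build_session_schedule(session, seed=0)
    targets = sched.target_events
    n_pos = sum(e.valence == "positive" for e in targets)
    onsets = trial_onsets(sched)
    print(f"Session {session}: {len(targets)} target events, "
          f"{n_pos} positive / {len(targets) - n_pos} negative, "
          f"span {sched.span_s:.0f} s")
    print(f"  first task onset {onsets[0]:.1f} s, trial period "
          f"{onsets[1] - onsets[0]:.0f} s, {len(onsets)} trials")

# The 30% minority class matches the session's warning face, so the
# participant hunts for session-congruent images among distractors.
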