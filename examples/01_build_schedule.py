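"""Build and validate a constrained temporal-bisection trial schedule.

The experimental phase presents 8 blocks; each block contains all 28
duration x condition combinations (7 durations x 4 sound conditions) in a
pseudo-random order with no two consecutive trials from the same
condition.
"""

from collections import Counter

from tempobisect import build_experiment_schedule, build_training_schedule, validate_schedule

training = build_training_schedule(seed=42)
print(f"training phase: {len(training.trials)} trials "
      f"(each exemplar once at 2 s and once at 5 s)")

schedule = build_experiment_schedule(seed=42)
print(f"experimental phase: {len(schedule.trials)} trials in {schedule.n_blocks} blocks")

durations = Counter(t.duration for t in schedule.trials)
print("presentations per duration:", dict(sorted(durations.items())))

violations = validate_schedule(schedule)
print(f"constraint violations: {violations!r}  (empty list = valid)")

print("\nfirst five trials:")
for t in schedule.trials[:5]:
    print(f"  block {t.block_index}  {t.condition.key:26s} "
          f"{t.exemplar_id:16s} {t.duration:.1f} s  (iti {t.iti:.2f} s)")
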