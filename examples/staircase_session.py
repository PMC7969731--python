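"""A behavioral test session: 2-down 1-up staircases and the learning score.

Simulates an observer doing three staircase blocks before and three after
perceptual training that lowers the detection threshold by 30%.  Each
block starts at 25% signal-to-noise ratio, steps down after two
consecutive correct responses and up after any error, and stops at the
tenth reversal; the block threshold is the geometric mean of the last six
reversal levels.  The performance improvement is the relative drop of the
day's mean threshold, (pre - post) / pre.
"""

from awakerest import behavior, synthetic

config = behavior.StaircaseConfig()
observer_pre = synthetic.ObserverModel(threshold_snr=0.06)
observer_post = observer_pre.with_threshold(0.06 * 0.7)  # 30% learning

pre_blocks = [behavior.run_staircase(config, observer_pre, seed) for seed in (1, 2, 3)]
post_blocks = [behavior.run_staircase(config, observer_post, seed) for seed in (4, 5, 6)]

for day, blocks in [("before training", pre_blocks), ("after training", post_blocks)]:
    for i, b in enumerate(blocks, 1):
        print(f"{day}, block {i}: {b.n_trials} trials, "
              f"threshold S/N = {b.threshold:.4f}")

score = behavior.performance_improvement(pre_blocks, post_blocks)
print(f"\nthreshold before: {score.threshold_pre:.4f}  "
      f"after: {score.threshold_post:.4f}")
print(f"performance improvement: {score.improvement:.2f} "
      f"(planted: 0.30; positive = learning)")
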