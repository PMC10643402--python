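"""Build the four stimulus schedules and inspect their structure.

Prints trial counts, deviant statistics and inter-onset spacing for the
pure-tone, oddball, many-standards and standard-block paradigms.
"""

import numpy as np

import dmmn

pure = dmmn.make_pure_tone_schedule(seed=0)
print(f"pure-tone: {len(pure)} tones, SOA {pure.soa} s, "
      f"durations {set(pure.durations_ms)} ms")

odd = dmmn.make_oddball_schedule(2000.0, seed=0)
n_dev = sum(r == "deviant" for r in odd.roles)
print(f"oddball @2 kHz: {len(odd)} trials, {n_dev} deviants "
      f"({100 * n_dev / len(odd):.1f}%), SOA "
      f"{np.diff(odd.onsets)[0] * 1000:.0f} ms")

ms = dmmn.make_many_standards_schedule(2000.0, seed=0)
print(f"many-standards: {len(ms)} trials, mean duration "
      f"{ms.durations_ms.mean():.1f} ms (design mean 113.5 ms)")

blocks = dmmn.make_standard_block_schedule(2000.0, soa=0.35, n_blocks=16)
gaps = np.diff(blocks.onsets)
print(f"standard blocks: {len(blocks)} tones, within-block spacing "
      f"{gaps.min():.2f} s, inter-block gap {gaps.max():.1f} s")

# The deviant fraction converges to 10% per trial; the mean deviant count
# per 165-s session is 30 by design (300 trials x 0.1).
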