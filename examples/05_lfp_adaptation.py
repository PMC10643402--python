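"""Event-related LFP: deviance on binned amplitudes and SOA-dependent
stimulus-specific adaptation.

Standard-block sessions at SOAs of 550 and 350 ms are simulated with
core-like adaptation parameters.  At 550 ms recovery between tones is
nearly complete and no position is significantly attenuated; at 350 ms
every later position is attenuated relative to the first tone of the
block, matching the closed-form steady state of the resource model.
"""

import numpy as np

import dmmn

params = dmmn.synthetic.AREA_ADAPTATION["core"]
for soa, n_blocks in ((0.55, 18), (0.35, 16)):
    sched = dmmn.make_standard_block_schedule(2000.0, soa=soa,
                                              n_blocks=n_blocks)
    trace, t = dmmn.simulate_lfp(sched, "core", seed=0)
    binned = dmmn.bin_lfp(trace, 24_000, sched, trace_start_s=t[0])
    res = dmmn.adaptation_by_position(binned)
    att = float(np.mean(1 - res.amplitudes[1:] / res.amplitudes[0]))
    closed = 1 - dmmn.steady_state_adaptation(params["u"], params["tau"], soa)
    print(f"SOA {soa*1000:.0f} ms: {res.significant.sum()}/9 later positions "
          f"significantly attenuated (FDR q=0.05); measured attenuation "
          f"{100*att:.2f}% vs closed-form {100*closed:.2f}%")

# RPB-like parameters recover slowly and stay suppressed even at 550 ms:
p = dmmn.synthetic.AREA_ADAPTATION["RPB"]
ss = dmmn.steady_state_adaptation(p["u"], p["tau"], 0.55)
print(f"RPB steady-state resource at SOA 550 ms: {ss:.2f} "
      f"(~{100*(1-ss):.0f}% suppression, duration-independent)")
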