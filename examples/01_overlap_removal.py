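"""Overlap removal when combining stimulus- and response-aligned ERPs.

A 500 ms stimulus-aligned epoch and a 500 ms response-aligned epoch (ending
100 ms before articulation) jointly cover a trial only if the production
latency is at least 1100 ms; for faster trials the two windows overlap and
the overlapping signal is removed from the response-aligned side.
"""

import erptopo as et

spec = et.CombineSpec(stim_len_ms=500, resp_len_ms=500, resp_offset_ms=100)

for rt in (600, 850, 1100, 1300):
    try:
        w = et.combined_window(rt, spec)
        print(f"RT {rt:5d} ms: remove {w.removed_ms:5.0f} ms, keep response "
              f"window {w.resp_keep_start_ms:6.0f}..{w.resp_keep_end_ms:.0f} ms")
    except et.CombineError as exc:
        print(f"RT {rt:5d} ms: {exc}")

# For RT 850 the response epoch natively covers -600..-100 ms, i.e.
# 250..750 ms after picture onset; its first 250 ms duplicate the stimulus
# epoch and are dropped, leaving -350..-100 ms. The combined ERP then spans
# picture onset to 100 ms before articulation with no overlap and no gap.
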