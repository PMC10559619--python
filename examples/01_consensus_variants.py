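"""Consensus structural-variant merging between two callers.

Builds a synthetic tumor with 60 true copy-number events, emits them
into two call sets with 20 bp breakpoint jitter plus caller-private
false positives, duplicates a fifth of the events into the wildtype
strain background, then merges: calls must agree within 100 bp at both
breakpoints, be longer than 10 kb, have MAPQ >= 60, and have no
wildtype counterpart.
"""

from gemmomics import synthdata as sd
from gemmomics import variants as va

cfg = sd.SynthConfig(seed=7, n_sv_events=60, sv_jitter_sd=20.0,
                     fp_rate=0.3, wt_frac=0.2)
res = sd.gen_sv_callsets(cfg, kind="CNV")

consensus = va.consensus_svs(res.caller_a, res.caller_b, res.wildtype)
n_truth = len(res.truth)
n_somatic = int((~res.truth.in_wildtype).sum())

print(f"caller A calls:        {len(res.caller_a)}")
print(f"caller B calls:        {len(res.caller_b)}")
print(f"true events:           {n_truth} ({n_truth - n_somatic} also in wildtype)")
print(f"consensus calls:       {len(consensus)}")
print(f"recall vs somatic truth: {len(consensus) / n_somatic:.2f}")

# Caller-private false positives never agree between callers, and the
# wildtype-matched events are subtracted, so the consensus should
# recover exactly the somatic truth set.
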