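"""Call de novo mutations in one simulated trio.

Candidates are Mendelian violations (child carries an allele absent from
both parents); a high-confidence call must pass a binomial
genotype-likelihood posterior test AND a heuristic depth/allele-balance
filter, with at least 10 reads carrying the mutation.
"""

import numpy as np

import dnmsuite as d
from dnmsuite import trio_caller

config = d.SimulationConfig()
trio = d.generate_trio(config, d.RateModel(), np.random.default_rng(7),
                       "T001")
candidates = trio_caller.candidate_sites(trio.sites)
calls = trio_caller.consensus_calls(trio.sites)

truth = set(zip(trio.truth["chrom"], trio.truth["pos"]))
called = {(c.chrom, c.pos) for c in calls}
print(f"sites in trio VCF:        {len(trio.sites)}")
print(f"Mendelian candidates:     {len(candidates)}")
print(f"high-confidence calls:    {len(calls)}")
print(f"true DNMs:                {len(truth)}")
print(f"recall:                   {len(called & truth) / len(truth):.3f}")
print(f"false positives:          {len(called - truth)}")
# at 38x a few true DNMs fall below the 10-alt-read or balance filters;
# no inherited variant survives the consensus
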