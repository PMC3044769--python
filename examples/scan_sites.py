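"""Candidate-site discovery and the seed filter in human and fly modes.

A site carrying one GU wobble opposite the miRNA seed (nt 2-7) is rejected
under the strict human rule but accepted under the fly rule, which tolerates
a single wobble.
"""

from mirneq import load_parameters, scan_candidate_sites
from mirneq.fixtures import FixtureSpec, make_fixture

params = load_parameters()
mirna, mrna, truth = make_fixture(FixtureSpec(rng_seed=23, site_kind="seed_gu"))
print(f"miRNA: {mirna}")
print(f"seed (nt 2-7): {mirna[1:7]}   planted site: {truth} with one G:U in the seed\n")

for mode in ("human", "fly"):
    sites = scan_candidate_sites(mirna, mrna, params, mode=mode)
    print(f"{mode} mode: {len(sites)} site(s)")
    for s in sites:
        lo, hi = s.alignment.site_interval
        print(
            f"  site {lo + 1}-{hi}  dg_hybrid = {s.alignment.dg_hybrid:.2f} kcal/mol"
            f"  seed GU count = {s.seed_gu_count}"
        )
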