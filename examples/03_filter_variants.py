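"""Somatic post-filters: panel-of-normals Fisher test and thresholds.

Simulated artefact sites carry the alternate allele in the panel of
normals at a tumour-like ratio, so Fisher's exact test cannot reject
ratio equality and the call is filtered; genuine somatic sites differ
sharply and are kept.
"""

from tgctevo.filters import pon_fisher_filter, threshold_filters
from tgctevo.simulate import SimulationConfig, simulate_pon_sites

config = SimulationConfig(seed=3, pon_artefact_rate=0.3)
sites = simulate_pon_sites(config, n_sites=200)

tp = fp = tn = fn = 0
for variant, pon, is_artefact in sites:
    decision = pon_fisher_filter(variant, pon)
    if is_artefact:
        tn += not decision.keep
        fn += decision.keep
    else:
        tp += decision.keep
        fp += not decision.keep
print(f"kept true somatic calls      : {tp}/{tp + fp}")
print(f"filtered recurrent artefacts : {tn}/{tn + fn}")

variants = [v for v, _, _ in sites[:10]]
kept, audit = threshold_filters(
    variants,
    germline_af={(variants[1].chrom, variants[1].pos): 0.02},
    somatic_freq={(variants[4].chrom, variants[4].pos): 0.06},
)
print(f"threshold filters: {len(kept)}/10 survive, audit {audit}")
print("\nGermline AF >= 1% and cohort somatic frequency >= 5% are removed;")
print("the PoN test keeps only calls whose tumour allele ratio differs.")
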