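"""Simulate one TGCT-like tumour genome and write its observable files.

Builds a whole-genome-duplicated tumour with known purity, doubling
time and per-variant multiplicities, then writes the Battenberg-style
segment table and the tumour/normal VCF the analysis modules read.
"""

from tgctevo.simulate import SimulationConfig, simulate_tumour, write_tumour

config = SimulationConfig(seed=11, chromosomes=("1", "2", "3"), mu=0.3,
                          wgd_probability=1.0, t_wgd=0.08)
sim = simulate_tumour(config, sample_id="DEMO-0001")
paths = write_tumour(sim, "scratch/demo")

pp = sim.purity_ploidy
print(f"sample            : {sim.sample_id}")
print(f"purity / ploidy   : {sim.purity:.3f} / {pp.ploidy:.2f}")
print(f"WGD (truth)       : {sim.is_wgd} at molecular time {sim.t_wgd}")
print(f"somatic SNVs      : {len(sim.variants)}")
print(f"pre-WGD mutations : {sim.n_pre_wgd} (truth)")
print(f"files             : {paths}")
print("\nThe VCF holds tumour/normal AD depths; the segment TSV carries")
print("allele-specific copy number with purity/ploidy header comments.")
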