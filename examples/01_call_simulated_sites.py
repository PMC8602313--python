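"""Call single-cell SNV events on a small simulated dataset.

Simulates an MDA-amplified single cell with a matched bulk, computes the
seven-event posterior at every candidate site, and prints a few calls.
"""

from mdacall import SimConfig, simulate_dataset, site_posteriors, genotype_call

ds = simulate_dataset(SimConfig(n_sites=500, seed=7))

print(f"{'pos':>5} {'truth':>8} {'call':>8} {'posterior':>9}  top event")
shown = 0
for pileup, row in zip(ds.pileups, ds.truth.itertuples()):
    if row.genotype == "hom_ref" and shown >= 5:
        continue  # mostly show the interesting sites
    ep = site_posteriors(pileup)
    call = genotype_call(ep)
    top = max(ep.probs, key=ep.probs.get)
    print(
        f"{row.pos:>5} {row.genotype:>8} {call.genotype:>8} "
        f"{call.posterior:>9.4f}  {top}"
    )
    shown += 1
    if shown >= 25:
        break
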