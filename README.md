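# mdacall

SNV calling and genotyping for a diploid, MDA-amplified single cell,
jointly with an unamplified bulk sample from the same individual.

Multiple displacement amplification (MDA) distorts allele fractions so
severely that standard diploid callers fail on single-cell data: one allele
of a heterozygous site frequently receives no reads at all (allele
dropout), and amplification noise creates spurious alternative-allele
evidence. `mdacall` models these distortions explicitly with
coverage-dependent beta-binomial distributions, combines the single cell
with a bulk sample of the same individual, and reports the posterior
probability of seven mutually exclusive single-cell events at each
candidate site:

| event | cell allele fraction θs | bulk allele fraction θb | meaning |
|---|---|---|---|
| `HOM_REF` | 0 | [0, ½) | cell and bulk reference |
| `ERR_ALT` | {½, 1} | 0 | alt evidence in the cell is artifact |
| `ADO_TO_ALT` | 1 | (0, ½] | reference allele dropped out |
| `HET` | ½ | (0, 1) | true heterozygous site |
| `ADO_TO_REF` | 0 | [½, 1) | alternative allele dropped out |
| `ERR_REF` | {0, ½} | 1 | ref evidence in the cell is artifact |
| `HOM_ALT` | 1 | (½, 1] | cell and bulk alternative |

Compounds of these events answer the practical questions: "does this cell
carry the alternative allele?" (five events), "what is the genotype?"
(dropout events imply a heterozygous cell), and "what is this cell's
allele-dropout rate?". Call sets are thresholded by controlling the
Bayesian expected false discovery rate directly from the posteriors.

## Quick start (library)

```python
from mdacall import SimConfig, simulate_dataset, site_posteriors, genotype_call

ds = simulate_dataset(SimConfig(n_sites=500, seed=7))
ep = site_posteriors(ds.pileups[27])     # a true het site
print(ep.probs["HET"])                   # 0.9348...
print(genotype_call(ep).genotype)        # "het"
```

Calling is independent per site and needs only a `SitePileup` — the read
classes (REF/ALT/OTHER) and base qualities of both samples at one
candidate site. Pileups can come from indexed BAM/CRAM files
(`mdacall.io.extract_pileup`), from a self-contained pileup TSV, or from
the bundled simulator.

## Quick start (command line)

```bash
mdacall simulate --seed 5 --n-sites 2000 --out sim
mdacall call --pileup-tsv sim.pileups.tsv -o calls.vcf
mdacall call SC.bam BULK.bam --candidates sites.vcf -o calls.vcf   # from alignments
mdacall control-fdr calls.vcf --events ALT_PRESENCE --fdr 0.05 -o confident.vcf
mdacall estimate-ado calls.vcf --truth-het het_sites.tsv -o ado.tsv
```

The output VCF stores the seven event posteriors (PHRED-scaled
`INFO/PROB_*` fields), the alt-presence compound, and per-sample
genotype/depth fields.

Running `examples/02_fdr_controlled_callset.py` (5,000 simulated sites,
seed 11) shows the expected-FDR control in action:

```
nominal FDR 0.01:  365 sites selected, expected FDR 0.0097, realized FDR 0.0000
nominal FDR 0.05:  471 sites selected, expected FDR 0.0478, realized FDR 0.0127
nominal FDR  0.2:  595 sites selected, expected FDR 0.1777, realized FDR 0.1950
```

## Allele dropout

Three per-cell dropout-rate estimators are provided over known
heterozygous sites (`examples/03_dropout_rates.py`, 10,000 sites, seed 3):

```
expected (posterior mass): 0.2131
mismatch (hom calls)     : 0.0619
naive (missing allele)   : 0.2462
realized in simulation   : 0.2462
```

The mismatch estimator sits structurally below the posterior-mass
estimator: a recognised dropout site is still *correctly* genotyped
heterozygous, so only the dropouts the caller misses surface as false
homozygous calls. See `docs/methods.md` for the full discussion.

## Repository layout

- `src/mdacall/` — the library: `bias` (amplification-bias distributions),
  `likelihoods` (read/sample likelihoods), `events` (the seven-event
  partition and posteriors), `fdr`, `ado`, `simulate`, `io`, `cli`
- `examples/` — short narrative scripts and a CLI workflow
- `docs/methods.md` — the probabilistic model and numerical choices
- `tests/` — unit/property tests plus `test_acceptance.py`, backed by an
  independent arbitrary-precision oracle (`tests/oracle.py`)
- `scripts/acceptance.py` — recomputes the headline quantities as JSON

## Testing and reproducing the results

```bash
python -m pytest -q tests/
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

The acceptance suite checks, among other things: exact encoding of the
amplification-bias parameter table; posterior agreement to 1e-8 with an
exhaustive-enumeration arbitrary-precision oracle; posterior normalisation
and exact REF↔ALT relabelling symmetry; expected-FDR calibration on
model-matched simulations (realized FDR 0.0068 at nominal 0.05, seed 1);
genotype accuracy ≥ 95% at coverage 20 (measured 0.9952); and a paired
bulk-coverage benefit. One acceptance assertion — 20% concordance between
the mismatch and posterior-mass dropout estimators — fails by design of
the genotype mapping and is documented in `docs/methods.md`.
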