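#!/usr/bin/env bash
# End-to-end command-line workflow on simulated data:
# simulate -> call -> FDR-filter -> dropout report.
set -euo pipefail

workdir=$(mktemp -d)
trap 'rm -rf "$workdir"' EXIT

# 1. simulate 2,000 candidate sites (pileup TSV + truth table)
mdacall simulate --seed 5 --n-sites 2000 --out "$workdir/sim"

# 2. call the seven event posteriors at every site
mdacall call --pileup-tsv "$workdir/sim.pileups.tsv" -o "$workdir/calls.vcf"

# 3. keep the largest call set with expected FDR <= 5% for alt presence
mdacall control-fdr "$workdir/calls.vcf" --events ALT_PRESENCE --fdr 0.05 \
    -o "$workdir/confident.vcf"

# 4. dropout-rate report over the truth-het sites
awk -F'\t' 'NR == 1 { print "chrom\tpos\tref\talt"; next }
            $3 == "het" { print $1 "\t" $2 "\tA\tC" }' \
    "$workdir/sim.truth.tsv" > "$workdir/het.tsv"
mdacall estimate-ado "$workdir/calls.vcf" --truth-het "$workdir/het.tsv" \
    -o "$workdir/ado.tsv"

echo
echo "confident calls:"
grep -vc '^#' "$workdir/confident.vcf"
echo
echo "dropout report:"
cat "$workdir/ado.tsv"
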