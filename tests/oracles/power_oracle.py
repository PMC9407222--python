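"""Brute-force power oracle for the private-allele enrichment scan.

Monte-Carlo simulation of the scan's generative model, written directly
against the closed-form site process (Poisson counts + exact binomial
tail) with no use of the package under test.  It produces the thresholds
frozen in ``tests/fixtures/power_thresholds.json``:

* ``min_recall``   — 0.5th percentile of the number of target genes called
                     significant (out of ``n_targets``),
* ``max_false_sig`` — 99.5th percentile of the number of non-target genes
                     called significant.

Conditions mirror the power-analysis configuration: 500 genes with 2-kb
total flanks on a 3-Mb genome, background private rate 2e-3 per bp,
20 target genes enriched 10-fold, exact one-sided binomial test at
alpha = 0.01 with the rate estimated genome-wide from the realized totals.

Run from the repository root:  python tests/oracles/power_oracle.py
"""
import json
import os

import numpy as np
from scipy import stats

N_GENES = 500
N_TARGETS = 20
FLANK_LEN = 2000
GENOME_LEN = 3_000_000
RATE = 2e-3
ENRICHMENT = 10.0
ALPHA = 0.01
N_REPS = 5000
SEED = 2024


def one_rep(rng):
    n_null = N_GENES - N_TARGETS
    null_counts = rng.poisson(RATE * FLANK_LEN, size=n_null)
    target_counts = rng.poisson(RATE * ENRICHMENT * FLANK_LEN, size=N_TARGETS)
    # background outside all flanks
    outside_len = GENOME_LEN - N_GENES * FLANK_LEN
    outside = rng.poisson(RATE * outside_len)
    total = null_counts.sum() + target_counts.sum() + outside
    rate_hat = total / GENOME_LEN
    p_null = stats.binom.sf(null_counts - 1, FLANK_LEN, rate_hat)
    p_target = stats.binom.sf(target_counts - 1, FLANK_LEN, rate_hat)
    return int((p_target < ALPHA).sum()), int((p_null < ALPHA).sum())


def main():
    rng = np.random.default_rng(SEED)
    recalls, false_sigs = [], []
    for _ in range(N_REPS):
        r, f = one_rep(rng)
        recalls.append(r)
        false_sigs.append(f)
    recalls = np.array(recalls)
    false_sigs = np.array(false_sigs)
    out = {
        "conditions": {
            "n_genes": N_GENES,
            "n_targets": N_TARGETS,
            "flank_len": FLANK_LEN,
            "genome_len": GENOME_LEN,
            "rate": RATE,
            "enrichment": ENRICHMENT,
            "alpha": ALPHA,
            "n_reps": N_REPS,
            "seed": SEED,
        },
        "min_recall": int(np.percentile(recalls, 0.5)),
        "median_recall": int(np.median(recalls)),
        "max_false_sig": int(np.percentile(false_sigs, 99.5)),
        "median_false_sig": int(np.median(false_sigs)),
    }
    path = os.path.join(os.path.dirname(__file__), "..", "fixtures", "power_thresholds.json")
    with open(os.path.abspath(path), "w") as fh:
        json.dump(out, fh, indent=2)
        fh.write("\n")
    print(json.dumps(out, indent=2))


if __name__ == "__main__":
    main()
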