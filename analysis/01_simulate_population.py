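#!/usr/bin/env python
"""Simulate the ground-truth neuron populations used throughout the analysis.

Draws (a) a 2038-neuron multiplex population from the joint
ASIC1a/ASIC2b/ASIC3 combination probabilities and (b) 500-neuron
single-marker populations with the per-marker ASIC3 expression
probabilities, and writes them as per-neuron CSV tables.
"""

from pathlib import Path

from drgquant import popsim
from drgquant.popsim import population_to_frame, sample_population

OUT = Path("results/populations")
SEED = 20240101


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    params = popsim.multiplex_coexpression_params()
    pop = sample_population(params, 2038, seed=SEED)
    population_to_frame(pop, params.probes).to_csv(OUT / "multiplex_2038.csv", index=False)
    truth = {}
    for nr in pop:
        truth[nr.truth_combo()] = truth.get(nr.truth_combo(), 0) + 1
    print(f"multiplex population: 2038 neurons -> {OUT / 'multiplex_2038.csv'}")
    for combo, count in sorted(truth.items(), key=lambda kv: -kv[1]):
        print(f"  {combo:>22}: {count:4d} ({100 * count / 2038:5.2f}%)")

    for marker in ("NF200", "CGRP", "IB4"):
        sp = popsim.asic3_marker_params(marker)
        spop = sample_population(sp, 500, seed=SEED + hash(marker) % 1000)
        population_to_frame(spop, ("ASIC3",)).to_csv(OUT / f"asic3_{marker}.csv", index=False)
        frac = sum(nr.truth_expr["ASIC3"] for nr in spop) / 500
        print(f"{marker}: 500 neurons, true ASIC3+ fraction {100 * frac:.1f}% "
              f"(generating {100 * popsim.ASIC3_MARKER_PROBS[marker]:.0f}%)")


if __name__ == "__main__":
    main()
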