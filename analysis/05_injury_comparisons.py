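#!/usr/bin/env python
"""Sham-vs-cuff comparisons: segment-specific proportion and intensity shifts.

Builds a nerve-injury scenario in which, within the L4 segment only, cuff
surgery down-regulates ASIC1a and up-regulates ASIC1b in peptidergic
(CGRP+) neurons, and raises per-cell ASIC2b intensity 1.5-fold.  Per-DRG
percent-positive values are compared with the unpaired t-test (the DRG is
the experimental unit); per-cell corrected intensities with one-way ANOVA
plus Tukey pairs.  L5 serves as the unaffected control segment.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from drgquant import imsim, popsim, quant, stats
from drgquant.pipeline import quantify_population
from drgquant.popsim import ConditionEffect, PopulationParams, sample_population

OUT = Path("results")
SEED = 23
N_DRG = 8           # ganglia per condition x segment
NEURONS_PER_DRG = 60


def _params():
    return PopulationParams(
        probes=("ASIC1a", "ASIC1b"),
        marker_proportions={"CGRP": 0.6, "IB4": 0.4},
        expr_prob={("CGRP", "ASIC1a"): 0.30, ("CGRP", "ASIC1b"): 0.30,
                   ("IB4", "ASIC1a"): 0.0, ("IB4", "ASIC1b"): 0.0},
        soma_area_params={"CGRP": (450.0, 90.0), "IB4": (400.0, 90.0)},
        condition_effects=[
            ConditionEffect("L4", "CGRP", "ASIC1a", new_probability=0.12),
            ConditionEffect("L4", "CGRP", "ASIC1b", new_probability=0.55),
        ],
    )


def proportion_comparisons() -> pd.DataFrame:
    params = _params()
    rows = []
    rec = []
    for segment in ("L4", "L5"):
        per_drg = {"sham": {"ASIC1a": [], "ASIC1b": []}, "cuff": {"ASIC1a": [], "ASIC1b": []}}
        for d in range(N_DRG):
            naive = sample_population(params, NEURONS_PER_DRG, seed=SEED + 100 * d)
            for cond in ("sham", "cuff"):
                pop = popsim.apply_condition_effects(naive, params, cond, segment,
                                                     seed=SEED + 100 * d + 1)
                for probe in ("ASIC1a", "ASIC1b"):
                    pct = quant.marker_percentage_table(pop, probe, use="truth")["CGRP"]
                    per_drg[cond][probe].append(pct)
        for probe in ("ASIC1a", "ASIC1b"):
            res = stats.compare_proportions(per_drg["sham"][probe], per_drg["cuff"][probe])
            rows.append({"segment": segment, "probe": probe, "marker": "CGRP",
                         "sham_mean": res.groups["a"]["mean"], "cuff_mean": res.groups["b"]["mean"],
                         "t": res.statistic, "df": res.df, "p": res.pvalue})
            rec.append((segment, probe, res))
    table = pd.DataFrame(rows)
    for segment, probe, res in rec:
        verdict = "significant" if res.pvalue < 0.05 else "ns"
        print(f"{segment} CGRP {probe}: sham {res.groups['a']['mean']:.1f}% vs "
              f"cuff {res.groups['b']['mean']:.1f}%, t = {res.statistic:.2f}, "
              f"p = {res.pvalue:.4g} ({verdict})")
    return table


def intensity_comparisons() -> pd.DataFrame:
    params = PopulationParams(
        probes=("ASIC2b",),
        marker_proportions={"CGRP": 1.0},
        expr_prob={("CGRP", "ASIC2b"): 1.0},
        soma_area_params={"CGRP": (450.0, 60.0)},
        condition_effects=[ConditionEffect("L4", "CGRP", "ASIC2b", intensity_multiplier=1.5)],
    )
    groups = {}
    cfg, qcfg = imsim.SimulationConfig(), quant.QuantConfig()
    for segment in ("L4", "L5"):
        naive = sample_population(params, 40, seed=SEED + 7)
        for cond in ("sham", "cuff"):
            pop = popsim.apply_condition_effects(naive, params, cond, segment, seed=SEED + 8)
            quantify_population(pop, cfg, qcfg, probes=("ASIC2b",), seed=SEED + 9)
            groups[f"{cond}:{segment}"] = np.array(
                [nr.corrected_intensity["ASIC2b"] for nr in pop]
            )
    results = stats.compare_intensities(groups)
    anova = results[0]
    print(f"\nASIC2b intensity, one-way ANOVA F({anova.df[0]:.0f}, {anova.df[1]:.0f}) = "
          f"{anova.statistic:.2f}, p = {anova.pvalue:.3g}")
    rows = []
    for r in results[1:]:
        rows.append({"comparison": r.name, "mean_diff": r.statistic, "p_adj": r.pvalue})
        print(f"  {r.name}: diff = {r.statistic:.2f} i.u., p_adj = {r.pvalue:.3g}")
    return pd.DataFrame(rows)


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    props = proportion_comparisons()
    props.to_csv(OUT / "injury_proportions.csv", index=False)
    inten = intensity_comparisons()
    inten.to_csv(OUT / "injury_intensity_tukey.csv", index=False)
    print(f"\ntables -> {OUT / 'injury_proportions.csv'}, {OUT / 'injury_intensity_tukey.csv'}")


if __name__ == "__main__":
    main()
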