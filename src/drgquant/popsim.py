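"""Ground-truth populations of DRG neurons.

A simulated neuron carries a marker class (NF200, CGRP, IB4 or unlabeled),
a soma cross-sectional area, a per-probe true expression state, and a true
transcript (punctum) count per probe.  Expression states are generated in
one of two modes:

``bernoulli``
    independent per-probe Bernoulli draws with per-(marker, probe)
    probabilities — the single-probe assay setting, where per-marker
    positive percentages are the quantity of interest;
``multinomial``
    a joint draw over the :math:`2^P` on/off combinations of the probe
    panel — the multiplex assay setting, where the co-expression pie
    (e.g. triple-positive fraction) is the quantity of interest.

Soma areas are truncated Gaussians (areas must be positive); the study's
size histograms are well described by normal distributions.  Nerve-injury
("cuff") effects are expressed as per-(segment, marker, probe) changes in
expression probability or per-cell intensity multipliers, with sham
identical to naive.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

MARKERS = ("NF200", "CGRP", "IB4", "unlabeled")
PROBES = ("ASIC1a", "ASIC1b", "ASIC2a", "ASIC2b", "ASIC3")
SEGMENTS = ("L4", "L5", "pooled")
CONDITIONS = ("naive", "sham", "cuff")

_PROB_TOL = 1e-9

#: Default per-cell punctum count for an expressing neuron.  Uniform on
#: 5..20 keeps every true positive comfortably above the >=3-puncta
#: positivity rule while remaining a plausible transcript load.
DEFAULT_PUNCTA_POSITIVE = {k: 1.0 / 16 for k in range(5, 21)}

#: Default count for a non-expressing neuron: mostly zero with occasional
#: background dots, always below the positivity rule.
DEFAULT_PUNCTA_NEGATIVE = {0: 0.8, 1: 0.1, 2: 0.1}


def combo_label(probes_on: frozenset[str] | set[str]) -> str:
    """Canonical label for an expression combination ('none' if empty)."""
    if not probes_on:
        return "none"
    return "+".join(p for p in PROBES if p in probes_on) or "+".join(sorted(probes_on))


@dataclass
class ConditionEffect:
    """A localized nerve-injury effect on one (segment, marker, probe) cell group.

    ``marker`` may be a single class or a tuple of classes.  Exactly one of
    ``new_probability`` (replaces the expression probability) or
    ``intensity_multiplier`` (scales per-cell fluorescence) must be set.
    """

    segment: str
    marker: str | tuple[str, ...]
    probe: str
    new_probability: float | None = None
    intensity_multiplier: float | None = None

    @property
    def markers(self) -> tuple[str, ...]:
        return (self.marker,) if isinstance(self.marker, str) else tuple(self.marker)


@dataclass
class PopulationParams:
    """Generating parameters for a simulated DRG neuron population."""

    mode: str = "bernoulli"
    probes: tuple[str, ...] = PROBES
    marker_proportions: dict[str, float] = field(
        default_factory=lambda: {"NF200": 0.35, "CGRP": 0.30, "IB4": 0.25, "unlabeled": 0.10}
    )
    #: (marker, probe) -> P(expressing); bernoulli mode.
    expr_prob: dict[tuple[str, str], float] = field(default_factory=dict)
    #: frozenset of probes -> probability of that joint combination; multinomial mode.
    coexpr_probs: dict[frozenset[str], float] = field(default_factory=dict)
    #: marker -> (mean, sd) of the soma-area Gaussian, um^2.
    soma_area_params: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {m: (700.0, 150.0) for m in MARKERS}
    )
    #: optional (marker, probe) -> (mean, sd) override used in bernoulli
    #: mode when the population is simulated for a single probe.
    soma_area_by_probe: dict[tuple[str, str], tuple[float, float]] = field(default_factory=dict)
    puncta_count_given_positive: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_PUNCTA_POSITIVE)
    )
    puncta_count_given_negative: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_PUNCTA_NEGATIVE)
    )
    condition_effects: list[ConditionEffect] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.mode not in ("bernoulli", "multinomial"):
            raise ValueError(f"unknown expression mode {self.mode!r}")
        _check_prob_map("marker_proportions", self.marker_proportions, must_sum=True)
        for key, p in self.expr_prob.items():
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"expr_prob[{key}] = {p} outside [0, 1]")
        if self.mode == "multinomial":
            if not self.coexpr_probs:
                raise ValueError("multinomial mode requires coexpr_probs")
            _check_prob_map(
                "coexpr_probs",
                {combo_label(k): v for k, v in self.coexpr_probs.items()},
                must_sum=True,
            )
        _check_prob_map("puncta_count_given_positive", self.puncta_count_given_positive, must_sum=True)
        _check_prob_map("puncta_count_given_negative", self.puncta_count_given_negative, must_sum=True)
        for key, (mu, sd) in {**self.soma_area_params, **self.soma_area_by_probe}.items():
            if sd <= 0:
                raise ValueError(f"soma area sd for {key} must be > 0, got {sd}")
            if mu <= 0:
                raise ValueError(f"soma area mean for {key} must be > 0, got {mu}")
        for eff in self.condition_effects:
            for m in eff.markers:
                if m not in MARKERS:
                    raise ValueError(f"condition effect references unknown marker {m!r}")
            if eff.probe not in self.probes:
                raise ValueError(f"condition effect references unknown probe {eff.probe!r}")
            if (eff.new_probability is None) == (eff.intensity_multiplier is None):
                raise ValueError(
                    "condition effect needs exactly one of new_probability / intensity_multiplier"
                )


def _check_prob_map(name: str, probs: dict, must_sum: bool) -> None:
    for key, p in probs.items():
        if not (0.0 <= p <= 1.0):
            raise ValueError(f"{name}[{key}] = {p} outside [0, 1]")
    if must_sum and abs(sum(probs.values()) - 1.0) > _PROB_TOL:
        raise ValueError(f"{name} sums to {sum(probs.values())}, expected 1")


@dataclass
class NeuronRecord:
    """One simulated (or measured) neuron and everything the pipeline fills in."""

    id: int
    marker: str
    segment: str = "pooled"
    condition: str = "naive"
    soma_area: float = 700.0  # um^2
    truth_expr: dict[str, bool] = field(default_factory=dict)
    true_puncta: dict[str, int] = field(default_factory=dict)
    called_expr: dict[str, bool] = field(default_factory=dict)
    puncta_count: dict[str, int] = field(default_factory=dict)
    corrected_intensity: dict[str, float] = field(default_factory=dict)
    intensity_scale: dict[str, float] = field(default_factory=dict)

    def truth_combo(self) -> str:
        return combo_label(frozenset(p for p, on in self.truth_expr.items() if on))

    def called_combo(self) -> str:
        return combo_label(frozenset(p for p, on in self.called_expr.items() if on))


def _draw_discrete(rng: np.random.Generator, dist: dict[int, float], size: int) -> np.ndarray:
    values = np.array(sorted(dist))
    probs = np.array([dist[v] for v in values], dtype=float)
    return rng.choice(values, size=size, p=probs / probs.sum())


def _draw_area(rng: np.random.Generator, mean: float, sd: float) -> float:
    # rejection sampling of the >0 truncation; trivial rejection rate for
    # any plausible (mean, sd)
    for _ in range(1000):
        a = rng.normal(mean, sd)
        if a > 0:
            return float(a)
    raise RuntimeError(f"truncated-normal draw failed for mean={mean}, sd={sd}")


def sample_population(
    params: PopulationParams,
    n: int,
    seed: int,
    segment: str = "pooled",
    condition: str = "naive",
) -> list[NeuronRecord]:
    """Draw ``n`` ground-truth neurons; identical seed gives identical output.

    Marker classes are multinomial over ``marker_proportions``; expression
    states follow the configured mode; per-probe punctum counts are drawn
    from the positive/negative count distributions; soma areas are
    positive-truncated Gaussians.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    params.validate()
    rng = np.random.default_rng(np.random.SeedSequence(seed))

    markers = list(params.marker_proportions)
    marker_p = np.array([params.marker_proportions[m] for m in markers], dtype=float)
    drawn_markers = rng.choice(markers, size=n, p=marker_p / marker_p.sum())

    if params.mode == "multinomial":
        combos = list(params.coexpr_probs)
        combo_p = np.array([params.coexpr_probs[c] for c in combos], dtype=float)
        combo_idx = rng.choice(len(combos), size=n, p=combo_p / combo_p.sum())

    neurons: list[NeuronRecord] = []
    single_probe = params.probes[0] if len(params.probes) == 1 else None
    for i in range(n):
        marker = str(drawn_markers[i])
        if params.mode == "bernoulli":
            truth = {
                p: bool(rng.random() < params.expr_prob.get((marker, p), 0.0))
                for p in params.probes
            }
        else:
            on = combos[combo_idx[i]]
            truth = {p: p in on for p in params.probes}
        puncta = {
            p: int(
                _draw_discrete(
                    rng,
                    params.puncta_count_given_positive
                    if truth[p]
                    else params.puncta_count_given_negative,
                    1,
                )[0]
            )
            for p in params.probes
        }
        if single_probe is not None and (marker, single_probe) in params.soma_area_by_probe:
            mu, sd = params.soma_area_by_probe[(marker, single_probe)]
        else:
            mu, sd = params.soma_area_params[marker]
        neurons.append(
            NeuronRecord(
                id=i,
                marker=marker,
                segment=segment,
                condition=condition,
                soma_area=_draw_area(rng, mu, sd),
                truth_expr=truth,
                true_puncta=puncta,
                intensity_scale={p: 1.0 for p in params.probes},
            )
        )
    return neurons


def apply_condition_effects(
    pop: list[NeuronRecord],
    params: PopulationParams,
    condition: str,
    segment: str,
    seed: int = 0,
) -> list[NeuronRecord]:
    """Relabel a naive population as sham or cuff and apply injury effects.

    Sham is statistically identical to naive (labels change, nothing else).
    Under cuff, each configured effect either re-draws the expression state
    of the matching (segment, marker, probe) neurons at its new probability
    — with punctum counts re-drawn consistently — or scales their rendered
    per-cell intensity.  Neurons outside the listed groups are untouched.
    """
    if condition not in ("sham", "cuff"):
        raise ValueError(f"condition must be 'sham' or 'cuff', got {condition!r}")
    if segment not in SEGMENTS:
        raise ValueError(f"unknown segment {segment!r}")
    params.validate()
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    out = [copy.deepcopy(nr) for nr in pop]
    for nr in out:
        nr.condition = condition
        nr.segment = segment
    if condition == "sham":
        return out
    for eff in params.condition_effects:
        if eff.segment != segment:
            continue
        for nr in out:
            if nr.marker not in eff.markers:
                continue
            if eff.new_probability is not None:
                nr.truth_expr[eff.probe] = bool(rng.random() < eff.new_probability)
                dist = (
                    params.puncta_count_given_positive
                    if nr.truth_expr[eff.probe]
                    else params.puncta_count_given_negative
                )
                nr.true_puncta[eff.probe] = int(_draw_discrete(rng, dist, 1)[0])
            else:
                nr.intensity_scale[eff.probe] = (
                    nr.intensity_scale.get(eff.probe, 1.0) * eff.intensity_multiplier
                )
    return out


def population_to_frame(pop: list[NeuronRecord], probes: tuple[str, ...] | None = None) -> pd.DataFrame:
    """Tabulate a population, one row per neuron, booleans as 0/1."""
    if probes is None:
        probes = tuple(pop[0].truth_expr) if pop else PROBES
    rows = []
    for nr in pop:
        row: dict = {
            "id": nr.id,
            "marker": nr.marker,
            "segment": nr.segment,
            "condition": nr.condition,
            "soma_area": nr.soma_area,
        }
        for p in probes:
            row[f"truth_{p}"] = int(nr.truth_expr.get(p, False))
            row[f"true_puncta_{p}"] = nr.true_puncta.get(p, 0)
            row[f"called_{p}"] = int(nr.called_expr[p]) if p in nr.called_expr else pd.NA
            row[f"puncta_count_{p}"] = nr.puncta_count.get(p, pd.NA)
            row[f"intensity_{p}"] = nr.corrected_intensity.get(p, np.nan)
        rows.append(row)
    return pd.DataFrame(rows)


def frame_to_population(df: pd.DataFrame) -> list[NeuronRecord]:
    """Inverse of :func:`population_to_frame` (for CSV round-trips)."""
    probes = tuple(c[len("truth_"):] for c in df.columns if c.startswith("truth_"))
    pop = []
    for _, row in df.iterrows():
        nr = NeuronRecord(
            id=int(row["id"]),
            marker=str(row["marker"]),
            segment=str(row["segment"]),
            condition=str(row["condition"]),
            soma_area=float(row["soma_area"]),
            truth_expr={p: bool(row[f"truth_{p}"]) for p in probes},
            true_puncta={p: int(row[f"true_puncta_{p}"]) for p in probes},
            intensity_scale={p: 1.0 for p in probes},
        )
        for p in probes:
            if not pd.isna(row.get(f"called_{p}", pd.NA)):
                nr.called_expr[p] = bool(int(row[f"called_{p}"]))
            if not pd.isna(row.get(f"puncta_count_{p}", pd.NA)):
                nr.puncta_count[p] = int(row[f"puncta_count_{p}"])
            val = row.get(f"intensity_{p}", np.nan)
            if not pd.isna(val):
                nr.corrected_intensity[p] = float(val)
        pop.append(nr)
    return pop


def multiplex_coexpression_params() -> PopulationParams:
    """Joint three-probe combination probabilities of the multiplex assay.

    The reported pie over 2038 neurons: 15% ASIC2b-only, 14% ASIC3-only,
    20% ASIC1a/3, 18% ASIC2b/3, 10% triple-positive, with ASIC1a-only
    below 2% (1.5% here) and ASIC1a/2b below 1% (0.5% here); the remainder
    expresses none of the three probes.
    """
    probs = {
        frozenset(): 0.21,
        frozenset({"ASIC1a"}): 0.015,
        frozenset({"ASIC2b"}): 0.15,
        frozenset({"ASIC3"}): 0.14,
        frozenset({"ASIC1a", "ASIC2b"}): 0.005,
        frozenset({"ASIC1a", "ASIC3"}): 0.20,
        frozenset({"ASIC2b", "ASIC3"}): 0.18,
        frozenset({"ASIC1a", "ASIC2b", "ASIC3"}): 0.10,
    }
    return PopulationParams(
        mode="multinomial",
        probes=("ASIC1a", "ASIC2b", "ASIC3"),
        coexpr_probs=probs,
    )


#: Per-marker ASIC3 expression probabilities of the single-probe assay
#: (fraction of marker-positive neurons expressing ASIC3).
ASIC3_MARKER_PROBS = {"NF200": 0.73, "CGRP": 0.65, "IB4": 0.10}


def asic3_marker_params(marker: str) -> PopulationParams:
    """Single-probe (ASIC3) population of one marker class."""
    if marker not in ASIC3_MARKER_PROBS:
        raise ValueError(f"no reported ASIC3 probability for marker {marker!r}")
    return PopulationParams(
        mode="bernoulli",
        probes=("ASIC3",),
        marker_proportions={marker: 1.0},
        expr_prob={(marker, "ASIC3"): ASIC3_MARKER_PROBS[marker]},
        soma_area_params={marker: (700.0, 150.0)},
    )


def with_effects(params: PopulationParams, effects: list[ConditionEffect]) -> PopulationParams:
    """Copy of ``params`` carrying the given injury effects."""
    return replace(params, condition_effects=list(effects))
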