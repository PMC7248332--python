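"""End-to-end orchestration: population -> images -> spots -> calls -> tables.

The central entry point is :func:`quantify_population`, which takes
ground-truth neurons, renders each soma's puncta as a small image tile per
probe, runs peak detection, applies the >=3-puncta positivity rule, and
measures background-corrected circular-ROI intensities.  Everything the
acceptance checks and the command-line interface do is built from the
functions here.

All randomness flows from a single master seed through per-stage child
streams, so identical configuration and seed reproduce identical tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from drgquant import __version__
from drgquant.imsim import SimulationConfig, PSFModel, render_neuron_tile, render_section, write_field_image
from drgquant.popsim import (
    ConditionEffect,
    NeuronRecord,
    PopulationParams,
    combo_label,
    population_to_frame,
    sample_population,
)
from drgquant.quant import (
    QuantConfig,
    call_positive,
    classify_size,
    coexpression_table,
    estimate_background,
    marker_percentage_table,
    measure_mean_intensity,
)
from drgquant.spots import count_puncta_in_roi, detect_peaks

__all__ = [
    "PipelineConfig",
    "quantify_population",
    "run_pipeline",
    "make_fixtures",
    "write_csv_with_provenance",
]


def quantify_neuron_probe(
    neuron: NeuronRecord,
    probe: str,
    sim_cfg: SimulationConfig,
    quant_cfg: QuantConfig,
    rng: np.random.Generator,
) -> None:
    """Render, detect and measure one (neuron, probe); fills the record in place."""
    tile, soma_mask = render_neuron_tile(
        neuron.true_puncta.get(probe, 0),
        neuron.soma_area,
        sim_cfg,
        rng,
        intensity_scale=neuron.intensity_scale.get(probe, 1.0),
    )
    min_sep = max(1.0, sim_cfg.omega0_px)
    spots = detect_peaks(tile, sim_cfg.detect_threshold, min_sep)
    count = count_puncta_in_roi(spots, soma_mask)
    neuron.puncta_count[probe] = count
    neuron.called_expr[probe] = call_positive(count, quant_cfg)

    side = tile.shape[0]
    center = ((side - 1) / 2.0, (side - 1) / 2.0)
    soma_r_px = np.sqrt(neuron.soma_area / np.pi) / sim_cfg.px_um
    # physical 6.3-um ROI expressed in simulation pixels, shrunk only for
    # the rare soma too small to contain it
    r_tile = int(min(round(quant_cfg.roi_radius_um / sim_cfg.px_um), np.floor(soma_r_px) - 1))
    r_tile = max(r_tile, 2)
    neuron_mean = measure_mean_intensity(tile, center, quant_cfg, radius_px=r_tile)
    m = 3  # corner background regions sit in the puncta-free tile margin
    corners = [(m, m), (m, side - 1 - m), (side - 1 - m, m), (side - 1 - m, side - 1 - m)]
    background = estimate_background(tile, corners, quant_cfg, spots=spots, radius_px=2)
    neuron.corrected_intensity[probe] = neuron_mean - background


def quantify_population(
    pop: list[NeuronRecord],
    sim_cfg: SimulationConfig,
    quant_cfg: QuantConfig,
    probes: tuple[str, ...] | None = None,
    seed: int = 0,
) -> list[NeuronRecord]:
    """Run the imaging + detection + calling chain over a whole population.

    Each neuron is rendered on its own tile per probe — statistically
    equivalent to packing somata into shared fields for positivity and
    intensity purposes, and embarrassingly simple to reproduce.  Returns
    the same records with ``puncta_count``, ``called_expr`` and
    ``corrected_intensity`` filled.
    """
    if probes is None:
        probes = tuple(pop[0].truth_expr) if pop else ()
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    for neuron in pop:
        for probe in probes:
            quantify_neuron_probe(neuron, probe, sim_cfg, quant_cfg, rng)
    return pop


# ---------------------------------------------------------------------------
# configuration plumbing


@dataclass
class PipelineConfig:
    """Composite configuration for a full pipeline run."""

    population: PopulationParams = field(default_factory=PopulationParams)
    n_neurons: int = 200
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    quant: QuantConfig = field(default_factory=QuantConfig)
    seed: int = 0
    outdir: str = "results/pipeline"
    verbosity: int = 1

    def __post_init__(self) -> None:
        if self.n_neurons < 1:
            raise ValueError("n_neurons must be >= 1")
        self.population.validate()

    def config_hash(self) -> str:
        # scientific parameters only: where outputs go must not change them
        payload = {k: v for k, v in self.to_dict().items() if k not in ("outdir", "verbosity")}
        return hashlib.sha256(json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()[:12]

    def to_dict(self) -> dict:
        pop = dataclasses.asdict(self.population)
        pop["expr_prob"] = {f"{m}:{p}": v for (m, p), v in self.population.expr_prob.items()}
        pop["coexpr_probs"] = {combo_label(k): v for k, v in self.population.coexpr_probs.items()}
        pop["soma_area_params"] = {m: list(v) for m, v in self.population.soma_area_params.items()}
        pop["soma_area_by_probe"] = {
            f"{m}:{p}": list(v) for (m, p), v in self.population.soma_area_by_probe.items()
        }
        pop["condition_effects"] = [dataclasses.asdict(e) for e in self.population.condition_effects]
        return {
            "population": pop,
            "n_neurons": self.n_neurons,
            "sim": dataclasses.asdict(self.sim),
            "quant": dataclasses.asdict(self.quant),
            "seed": self.seed,
            "outdir": self.outdir,
            "verbosity": self.verbosity,
        }

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        pop_raw = dict(raw.get("population", {}))
        if "probes" in pop_raw:
            pop_raw["probes"] = tuple(pop_raw["probes"])
        if "expr_prob" in pop_raw:
            pop_raw["expr_prob"] = {
                tuple(k.split(":")): v for k, v in pop_raw["expr_prob"].items()
            }
        if "coexpr_probs" in pop_raw:
            pop_raw["coexpr_probs"] = {
                (frozenset() if k == "none" else frozenset(k.split("+"))): v
                for k, v in pop_raw["coexpr_probs"].items()
            }
        for key in ("soma_area_params",):
            if key in pop_raw:
                pop_raw[key] = {m: tuple(v) for m, v in pop_raw[key].items()}
        if "soma_area_by_probe" in pop_raw:
            pop_raw["soma_area_by_probe"] = {
                tuple(k.split(":")): tuple(v) for k, v in pop_raw["soma_area_by_probe"].items()
            }
        if "condition_effects" in pop_raw:
            pop_raw["condition_effects"] = [
                ConditionEffect(**e) for e in pop_raw["condition_effects"]
            ]
        sim_raw = dict(raw.get("sim", {}))
        if "psf" in sim_raw:
            sim_raw["psf"] = PSFModel(**sim_raw["psf"])
        return cls(
            population=PopulationParams(**pop_raw),
            n_neurons=int(raw.get("n_neurons", 200)),
            sim=SimulationConfig(**sim_raw),
            quant=QuantConfig(**raw.get("quant", {})),
            seed=int(raw.get("seed", 0)),
            outdir=str(raw.get("outdir", "results/pipeline")),
            verbosity=int(raw.get("verbosity", 1)),
        )

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        text = Path(path).read_text()
        raw = yaml.safe_load(text)  # YAML superset also parses JSON
        if not isinstance(raw, dict):
            raise ValueError(f"config {path} did not parse to a mapping")
        return cls.from_dict(raw)


def write_csv_with_provenance(df: pd.DataFrame, path: str | Path, meta: dict) -> None:
    """CSV preceded by '#'-commented provenance lines (tool, hash, seed)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    header = "".join(f"# {k}={v}\n" for k, v in meta.items())
    path.write_text(header + df.to_csv(index=False))


def read_csv_with_provenance(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def run_pipeline(config: PipelineConfig | str | Path) -> Path:
    """Execute population -> images -> detection -> quantification -> tables.

    Writes the per-neuron table plus the three summary tables (per-marker
    percent positive, size-class distribution of positives, co-expression
    pie) and a JSON run manifest into ``config.outdir``.  Identical
    config + seed give byte-identical CSVs.
    """
    if not isinstance(config, PipelineConfig):
        config = PipelineConfig.from_file(config)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta = {
        "tool": f"drgquant {__version__}",
        "config_hash": config.config_hash(),
        "seed": config.seed,
    }
    ss = np.random.SeedSequence(config.seed)
    pop_seed, quant_seed = (int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(2))

    pop = sample_population(config.population, config.n_neurons, seed=pop_seed)
    probes = config.population.probes
    quantify_population(pop, config.sim, config.quant, probes=probes, seed=quant_seed)

    per_neuron = population_to_frame(pop, probes)
    per_neuron["size_class"] = [classify_size(nr.soma_area, config.quant) for nr in pop]
    write_csv_with_provenance(per_neuron, outdir / "per_neuron.csv", meta)

    pct_rows = []
    for probe in probes:
        for marker, pct in marker_percentage_table(pop, probe).items():
            pct_rows.append({"probe": probe, "marker": marker, "percent_positive": pct})
    write_csv_with_provenance(pd.DataFrame(pct_rows), outdir / "marker_percentages.csv", meta)

    size_rows = []
    for probe in probes:
        pos = [nr for nr in pop if nr.called_expr.get(probe)]
        classes = [classify_size(nr.soma_area, config.quant) for nr in pos]
        for cls_name in ("small", "medium", "large"):
            size_rows.append(
                {
                    "probe": probe,
                    "size_class": cls_name,
                    "count": classes.count(cls_name),
                    "fraction": classes.count(cls_name) / len(classes) if classes else np.nan,
                }
            )
    write_csv_with_provenance(pd.DataFrame(size_rows), outdir / "size_classes.csv", meta)

    coexpr = coexpression_table(pop, probes)
    write_csv_with_provenance(coexpr, outdir / "coexpression.csv", meta)

    manifest = {
        **meta,
        "n_neurons": config.n_neurons,
        "probes": list(probes),
        "outputs": [
            "per_neuron.csv",
            "marker_percentages.csv",
            "size_classes.csv",
            "coexpression.csv",
        ],
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return outdir


def make_fixtures(seed: int, outdir: str | Path) -> dict:
    """Deterministically generate the small demonstration/test artifacts.

    Writes (1) a 256x256 two-emitter image, (2) an eight-neuron field with
    one neuron per three-probe expression combination, and (3) a
    2038-neuron multiplex population table.  Returns a manifest with
    SHA-256 checksums.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(seed)
    s1, s2, s3 = (int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(3))

    from drgquant.imsim import psf_render
    from drgquant.popsim import multiplex_coexpression_params

    cfg = SimulationConfig(noise_sd=0.0, seed=s1)
    counts = np.zeros((256, 256), dtype=int)
    counts[64, 64] = 1
    counts[192, 192] = 1
    two_emitter = psf_render(counts, cfg)
    write_field_image(two_emitter, outdir / "two_emitter.tif")

    probes = ("ASIC1a", "ASIC2b", "ASIC3")
    rng = np.random.default_rng(s2)
    neurons = []
    import itertools as it

    combos = [frozenset(c) for k in range(4) for c in it.combinations(probes, k)]
    for i, combo in enumerate(combos):
        neurons.append(
            NeuronRecord(
                id=i,
                marker="NF200",
                soma_area=600.0,
                truth_expr={p: p in combo for p in probes},
                true_puncta={p: (10 if p in combo else 0) for p in probes},
                intensity_scale={p: 1.0 for p in probes},
            )
        )
    marker_img, probe_img, labels = render_section(
        neurons, SimulationConfig(seed=s2), probe="ASIC3", field_size_um=140.0, rng=rng
    )
    write_field_image(marker_img, outdir / "eight_neuron_marker.tif")
    write_field_image(probe_img, outdir / "eight_neuron_ASIC3.tif")
    np.save(outdir / "eight_neuron_labels.npy", labels)

    pop = sample_population(multiplex_coexpression_params(), 2038, seed=s3)
    df = population_to_frame(pop, probes)
    df.to_csv(outdir / "population_2038.csv", index=False)

    manifest = {"seed": seed, "artifacts": {}}
    for name in (
        "two_emitter.tif",
        "eight_neuron_marker.tif",
        "eight_neuron_ASIC3.tif",
        "population_2038.csv",
    ):
        digest = hashlib.sha256((outdir / name).read_bytes()).hexdigest()
        manifest["artifacts"][name] = digest
    (outdir / "fixture_manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
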