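"""Run configuration and end-to-end pipeline orchestration.

A single global seed is fanned out to independent per-stage child seeds
through ``numpy.random.SeedSequence(seed).spawn``, so a change in one
stage's draw count never perturbs another stage. A full run writes, per
species and scaling: the suitability map, resistance surfaces, both
connectivity products, the stacked multi-species products, the
comparison matrices and proxy rankings, and a manifest recording every
parameter.
"""

from __future__ import annotations

import json
import logging
import os
import time
from dataclasses import asdict, dataclass, field

import numpy as np
import yaml  # type: ignore[import-untyped]

from . import io as cio
from .compare import comparison_matrix, proxy_ranking
from .connectivity import run_species_connectivity
from .raster import PredictorStack, PresenceSet, TerminalRegion
from .resistance import linear_resistance, nonlinear_resistance, normalize_stacked
from .sdm import (
    DEFAULT_FAMILIES,
    SuitabilityMap,
    ThinningConfig,
    collinearity_screen,
    fit_ensemble,
    generate_pseudo_absences,
    stack_suitability,
    thin_points,
)
from .synthetic import (
    make_predictor_stack,
    make_species_assemblage,
    make_terminals,
    sample_transect_presences,
    true_suitability,
)

__all__ = ["RunConfig", "run_pipeline", "run_assemblage_experiment", "stage_seed"]

logger = logging.getLogger("corridors")

_STAGES = (
    "landscape",
    "species",
    "sampling",
    "thinning",
    "pseudo_absence",
    "sdm",
    "connectivity",
)


def stage_seed(seed: int, stage: str, index: int = 0) -> int:
    """Deterministic per-stage child seed derived from the global seed."""
    if stage not in _STAGES:
        raise ValueError(f"unknown stage '{stage}'")
    k = _STAGES.index(stage)
    child = np.random.SeedSequence(seed, spawn_key=(k, index))
    return int(child.generate_state(1)[0] % (2**31))


@dataclass
class RunConfig:
    """Every tunable of a full synthetic pipeline run.

    The defaults are the synthetic study conditions: a 60x60 grid of
    1-km cells, seven species observed along 1-km-spaced north-south
    transects, geographic thinning at one cell size, equal-count random
    pseudo-absences, AUC-retention ensembles with a 70/30 holdout, and
    both resistance scalings crossed with both connectivity methods.
    """

    seed: int = 0
    shape: tuple[int, int] = (60, 60)
    cell_size: float = 1000.0
    n_species: int = 7
    n_smooth_fields: int = 4
    n_distance_fields: int = 4
    detection_scale: float = 0.5
    transect_spacing: float = 1000.0
    prevalence: float = 0.25
    families: tuple[str, ...] = DEFAULT_FAMILIES
    retention_auc: float = 0.90
    holdout_fraction: float = 0.30
    reps: int = 10
    thin_distance: float = 1000.0
    pseudo_absence_strategy: str = "random_equal"
    pseudo_absence_n: int | None = None
    scalings: tuple[str, ...] = ("linear", "nonlinear")
    methods: tuple[str, ...] = ("least_cost", "circuit")
    slice_fraction: float = 0.10
    connectivity: int = 8
    overlap_convention: str = "jaccard"
    terminal_fraction: float = 0.05

    def to_dict(self) -> dict:
        d = asdict(self)
        d["shape"] = list(self.shape)
        d["families"] = list(self.families)
        d["scalings"] = list(self.scalings)
        d["methods"] = list(self.methods)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        for key in ("shape", "families", "scalings", "methods"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class RunResult:
    """In-memory products of a pipeline run (also written to disk)."""

    config: RunConfig
    suitability: dict[str, SuitabilityMap]
    correlation: dict[tuple[str, str], "object"]  # (product, scaling) -> matrix
    overlap: dict[str, "object"]  # scaling -> matrix
    rankings: dict[tuple[str, str], "object"]
    manifest: dict
    out_dir: str | None = None


def _fit_species_maps(
    predictors: PredictorStack,
    specs,
    cfg: RunConfig,
) -> tuple[dict[str, SuitabilityMap], dict]:
    """Sample, thin, fit and predict for every species; returns maps and
    per-species diagnostics."""
    maps: dict[str, SuitabilityMap] = {}
    diagnostics: dict = {}
    grid = predictors.grid
    for i, spec in enumerate(specs):
        truth = true_suitability(spec, predictors)
        presences = sample_transect_presences(
            truth,
            transect_spacing=cfg.transect_spacing,
            detection_scale=cfg.detection_scale,
            seed=stage_seed(cfg.seed, "sampling", i),
            species=spec.name,
        )
        thinned = thin_points(
            presences,
            ThinningConfig(cfg.thin_distance),
            seed=stage_seed(cfg.seed, "thinning", i),
        )
        absences = generate_pseudo_absences(
            grid,
            thinned,
            strategy=cfg.pseudo_absence_strategy,
            n=cfg.pseudo_absence_n,
            seed=stage_seed(cfg.seed, "pseudo_absence", i),
        )
        model, smap = fit_ensemble(
            thinned,
            absences,
            predictors,
            families=cfg.families,
            retention_auc=cfg.retention_auc,
            holdout_fraction=cfg.holdout_fraction,
            reps=cfg.reps,
            seed=stage_seed(cfg.seed, "sdm", i),
        )
        maps[spec.name] = smap
        diagnostics[spec.name] = {
            "n_presences_raw": len(presences),
            "n_presences_thinned": len(thinned),
            "n_absences": len(absences),
            "learners": [
                {
                    "family": lr.family,
                    "mean_auc": lr.mean_auc,
                    "retained": lr.retained,
                }
                for lr in model.learners
            ],
        }
    return maps, diagnostics


def _connectivity_products(
    maps: dict[str, SuitabilityMap],
    a: TerminalRegion,
    b: TerminalRegion,
    cfg: RunConfig,
):
    """Resistance + connectivity for every (label, scaling) combination."""
    scalers = {"linear": linear_resistance, "nonlinear": nonlinear_resistance}
    products: dict = {}
    for label, smap in maps.items():
        base = normalize_stacked(smap) if smap.n_species > 1 else smap
        for scaling in cfg.scalings:
            res = scalers[scaling](base)
            corridor, circuit = run_species_connectivity(
                res,
                a,
                b,
                slice_fraction=cfg.slice_fraction,
                connectivity=cfg.connectivity,
            )
            products[(label, scaling)] = {
                "resistance": res,
                "corridor": corridor,
                "circuit": circuit,
            }
    return products


def _comparison_layer(maps, products, cfg: RunConfig):
    """All comparison matrices and proxy rankings for a finished run."""
    labels = list(maps)
    correlation = {}
    overlap = {}
    rankings = {}
    suit_products = {lb: maps[lb].grid for lb in labels}
    correlation[("suitability", "none")] = comparison_matrix(
        suit_products, "pearson_r", product="suitability"
    )
    for scaling in cfg.scalings:
        if "circuit" in cfg.methods:
            cur = {
                lb: products[(lb, scaling)]["circuit"].current for lb in labels
            }
            m = comparison_matrix(cur, "pearson_r", product="circuit", scaling=scaling)
            correlation[("circuit", scaling)] = m
            rankings[("circuit", scaling)] = proxy_ranking(m)
        if "least_cost" in cfg.methods:
            nl = {lb: products[(lb, scaling)]["corridor"].nlcc for lb in labels}
            m = comparison_matrix(
                nl, "pearson_r", product="least_cost_nlcc", scaling=scaling
            )
            correlation[("least_cost_nlcc", scaling)] = m
            rankings[("least_cost_nlcc", scaling)] = proxy_ranking(m)
            masks = {
                lb: products[(lb, scaling)]["corridor"].mask10 for lb in labels
            }
            om = comparison_matrix(
                masks,
                "percent_overlap",
                product="corridor_mask",
                scaling=scaling,
                overlap_convention=cfg.overlap_convention,
            )
            overlap[scaling] = om
            rankings[("corridor_mask", scaling)] = proxy_ranking(om)
    return correlation, overlap, rankings


def run_pipeline(cfg: RunConfig, out_dir: str | os.PathLike | None = None) -> RunResult:
    """Full synthetic run: landscape -> SDMs -> resistances -> connectivity
    -> comparisons, optionally written to an output directory."""
    t0 = time.time()
    logger.info("pipeline start: seed=%d shape=%s species=%d",
                cfg.seed, cfg.shape, cfg.n_species)

    predictors = make_predictor_stack(
        cfg.shape,
        cell_size=cfg.cell_size,
        n_smooth_fields=cfg.n_smooth_fields,
        n_distance_fields=cfg.n_distance_fields,
        seed=stage_seed(cfg.seed, "landscape"),
    )
    screen = collinearity_screen(predictors)
    a, b = make_terminals(predictors.grid, frac=cfg.terminal_fraction)
    specs = make_species_assemblage(
        predictors,
        n_species=cfg.n_species,
        seed=stage_seed(cfg.seed, "species"),
        prevalence=cfg.prevalence,
        detection_scale=cfg.detection_scale,
    )

    maps, diagnostics = _fit_species_maps(predictors, specs, cfg)
    stacked = stack_suitability(list(maps.values()))
    all_maps = dict(maps)
    all_maps["stacked"] = stacked

    products = _connectivity_products(all_maps, a, b, cfg)
    correlation, overlap, rankings = _comparison_layer(all_maps, products, cfg)

    manifest = {
        "config": cfg.to_dict(),
        "stage_seeds": {s: stage_seed(cfg.seed, s) for s in _STAGES},
        "species": [s.name for s in specs],
        "diagnostics": diagnostics,
        "lcp_cost": {
            f"{lb}_{sc}": products[(lb, sc)]["corridor"].lcp_cost
            for (lb, sc) in products
        },
        "effective_resistance": {
            f"{lb}_{sc}": products[(lb, sc)]["circuit"].effective_resistance
            for (lb, sc) in products
        },
        "wall_time_s": None,
    }

    if out_dir is not None:
        out_dir = str(out_dir)
        for sub in ("predictors", "suitability", "resistance", "connectivity",
                    "compare"):
            os.makedirs(os.path.join(out_dir, sub), exist_ok=True)
        cio.write_predictor_stack(predictors, os.path.join(out_dir, "predictors"))
        cio.write_mask(a, os.path.join(out_dir, "terminal_a.asc"), predictors.grid)
        cio.write_mask(b, os.path.join(out_dir, "terminal_b.asc"), predictors.grid)
        screen.to_csv(os.path.join(out_dir, "collinearity.csv"), index=False)
        for label, smap in all_maps.items():
            cio.write_raster(
                smap.grid, os.path.join(out_dir, "suitability", f"{label}.asc")
            )
        for (label, scaling), prod in products.items():
            cio.write_raster(
                prod["resistance"].grid,
                os.path.join(out_dir, "resistance", f"{label}_{scaling}.asc"),
            )
            cdir = os.path.join(out_dir, "connectivity")
            cio.write_raster(
                prod["corridor"].nlcc, os.path.join(cdir, f"{label}_{scaling}_nlcc.asc")
            )
            mask_grid = predictors.grid.with_values(
                prod["corridor"].mask10.astype(float),
                nodata_mask=np.zeros(predictors.grid.shape, dtype=bool),
            )
            cio.write_mask(mask_grid, os.path.join(cdir, f"{label}_{scaling}_mask.asc"))
            cio.write_raster(
                prod["circuit"].current,
                os.path.join(cdir, f"{label}_{scaling}_current.asc"),
            )
            cio.write_raster(
                prod["circuit"].voltage,
                os.path.join(cdir, f"{label}_{scaling}_voltage.asc"),
            )
        for (product, scaling), m in correlation.items():
            m.to_csv(
                os.path.join(out_dir, "compare", f"pearson_{product}_{scaling}.csv")
            )
        for scaling, m in overlap.items():
            m.to_csv(os.path.join(out_dir, "compare", f"overlap_{scaling}.csv"))
        for (product, scaling), rk in rankings.items():
            rk.to_csv(
                os.path.join(out_dir, "compare", f"ranking_{product}_{scaling}.csv"),
                index=False,
            )
        cfg.to_yaml(os.path.join(out_dir, "config.yaml"))

    manifest["wall_time_s"] = round(time.time() - t0, 3)
    if out_dir is not None:
        with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=2)
    logger.info("pipeline done in %.1fs", manifest["wall_time_s"])

    return RunResult(
        config=cfg,
        suitability=all_maps,
        correlation=correlation,
        overlap=overlap,
        rankings=rankings,
        manifest=manifest,
        out_dir=None if out_dir is None else str(out_dir),
    )



def run_assemblage_experiment(seed: int, cfg: RunConfig | None = None) -> RunResult:
    """One seeded multi-species experiment at the reduced study scale.

    Used for the generalist-proxy and scaling-robustness properties: a
    40x40 landscape, seven species (six specialists and one
    niche-centroid generalist), two fast learner families, three holdout
    repetitions, and the relaxed 0.5 retention threshold appropriate for
    noisy synthetic data.
    """
    if cfg is None:
        cfg = RunConfig(
            seed=seed,
            shape=(40, 40),
            n_species=7,
            n_smooth_fields=3,
            n_distance_fields=2,
            families=("logistic", "maxent"),
            retention_auc=0.5,
            reps=3,
            detection_scale=0.5,
        )
    else:
        cfg.seed = seed
    return run_pipeline(cfg, out_dir=None)
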