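"""End-to-end pipeline: occurrences -> optima -> screen -> selection -> PCA."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

import elevtrait
from elevtrait import io as eio
from elevtrait.hof import fit_all_species
from elevtrait.ppca import phylo_pca, project_categories
from elevtrait.screen import (PUBLISHED_TABLE, habitat_contrast_scan,
                              single_predictor_scan)
from elevtrait.selection import (DEFAULT_CATEGORIES, CategorySpec,
                                 sequential_selection)

log = logging.getLogger("elevtrait")

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    tree: str
    traits: str
    occurrences: str
    out_dir: str
    habitat: str = "both"            # steppe | alpine | both
    categories: tuple = DEFAULT_CATEGORIES
    transforms: dict | None = None   # trait -> none|sqrt|log; None = heuristic
    threshold_frac: float = 0.05
    alpha: float = 0.05
    seed: int = 0
    elev_range: tuple | None = None

    def __post_init__(self):
        if self.habitat not in ("steppe", "alpine", "both"):
            raise ValueError("habitat must be steppe, alpine, or both")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        cats = []
        for c in self.categories:
            cats.append(c if isinstance(c, CategorySpec)
                        else CategorySpec(c["name"], tuple(c["predictors"])))
        self.categories = tuple(cats)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["categories"] = [{"name": c.name, "predictors": list(c.predictors)}
                           for c in self.categories]
        return d


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write artifacts under ``config.out_dir``.

    Artifacts: optima.csv, scan_<habitat>.csv, contrasts.csv,
    ledger_<habitat>.json, ppca_<habitat>.json, run.json (config echo, hash,
    version, stage log).  Deterministic given config + seed.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = eio.config_hash(config.to_dict())
    stamp = {"config_hash": chash, "version": elevtrait.__version__}
    runlog = {"stages": [], **stamp, "config": config.to_dict()}

    def fail(stage, exc):
        runlog["stages"].append({"stage": stage, "status": f"error: {exc}"})
        with open(out / "run.json", "w") as fh:
            json.dump(runlog, fh, indent=2)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    tree = eio.read_tree(config.tree)
    traits = eio.read_traits(config.traits)
    occ = eio.read_occurrences(config.occurrences)

    report = eio.validate_inputs(tree, traits, occ, config.elev_range)
    runlog["validation"] = {"failures": report.failures,
                            "warnings": report.warnings}
    if not report.ok:
        fail("validate", ValueError(str(report)))

    habitats = (["steppe", "alpine"] if config.habitat == "both"
                else [config.habitat])

    # 1. elevational optima by HOF fits
    try:
        optima_tab = fit_all_species(occ, threshold_frac=config.threshold_frac)
        optima_tab.to_csv(out / "optima.csv", index=False)
        runlog["stages"].append({"stage": "optima", "status": "ok",
                                 "n_species": int(len(optima_tab))})
    except Exception as exc:
        fail("optima", exc)
    optima = optima_tab.set_index("species")["optimum_m"]

    analysis = traits.join(optima.rename("optimum"), how="inner")

    # 2. single-predictor screening + habitat contrasts
    try:
        scans = []
        for hab in habitats:
            scan = single_predictor_scan(analysis, optima, tree, hab,
                                         transforms=config.transforms,
                                         alpha=config.alpha)
            scan.to_csv(out / f"scan_{hab}.csv", index=False)
            scans.append(scan)
        if {"steppe", "alpine"} <= set(analysis["habitat"].astype(str)):
            contrasts = habitat_contrast_scan(analysis, tree, alpha=config.alpha)
            contrasts.to_csv(out / "contrasts.csv", index=False)
        runlog["stages"].append({"stage": "screen", "status": "ok"})
    except Exception as exc:
        fail("screen", exc)

    # 3. sequential category-wise selection per habitat
    ledgers = {}
    try:
        for hab in habitats:
            pool = analysis[analysis["habitat"] == hab]
            ledger = sequential_selection(pool, tree, config.categories,
                                          response="optimum")
            ledger.to_json(out / f"ledger_{hab}.json")
            with open(out / f"report_{hab}.txt", "w") as fh:
                fh.write(ledger.report() + "\n")
            ledgers[hab] = ledger
        runlog["stages"].append({"stage": "select", "status": "ok"})
    except Exception as exc:
        fail("select", exc)

    # 4. phylogenetic PCA per habitat (continuous traits + optimum/min/max)
    try:
        cont = [t for t in PUBLISHED_TABLE["trait"]
                if t in analysis.columns and t != "growth_form"]
        for hab in habitats:
            pool = analysis[analysis["habitat"] == hab]
            mat = pool[cont].join(
                optima_tab.set_index("species")[["optimum_m", "min_m", "max_m"]],
                how="inner").dropna()
            res = phylo_pca(mat, tree)
            payload = res.to_dict()
            if "growth_form" in pool.columns:
                cent = project_categories(res.scores,
                                          pool.loc[mat.index, "growth_form"])
                payload["centroids"] = {
                    i: row.drop("flag").to_dict() for i, row in cent.iterrows()
                }
            payload.update(stamp)
            with open(out / f"ppca_{hab}.json", "w") as fh:
                json.dump(payload, fh, indent=2)
        runlog["stages"].append({"stage": "ppca", "status": "ok"})
    except Exception as exc:
        fail("ppca", exc)

    with open(out / "run.json", "w") as fh:
        json.dump(runlog, fh, indent=2)
    return {"optima": optima_tab, "ledgers": ledgers, "runlog": runlog}
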