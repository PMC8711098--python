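"""Reproducible experiment runners: CV reports and hyperparameter grids.

These functions are the library layer behind the command-line interface:
they tie cohort I/O, the solvers and the evaluation battery into runs whose
every output artifact embeds provenance (package version, config hash,
seed), so a report can always be traced back to the exact configuration
that produced it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import itertools
import json
import logging
from pathlib import Path

import pandas as pd

from .cohort import CohortTable
from .evaluation import CVResult, kfold_cv
from .solver import Hyperparams

logger = logging.getLogger(__name__)


def _version() -> str:
    from . import __version__

    return __version__


def config_hash(config: dict) -> str:
    """Stable short hash of a JSON-serializable configuration."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def provenance(config: dict, seed: int) -> dict:
    return {
        "package_version": _version(),
        "config_hash": config_hash(config),
        "seed": seed,
    }


def run_cv_experiment(
    cohort: CohortTable,
    hp: Hyperparams,
    folds: int,
    seed: int,
    out_dir,
    model_kinds: tuple[str, ...] = ("mlaprbfn",),
) -> dict[str, CVResult]:
    """Run k-fold CV for each requested model and write the report files.

    Writes per model: ``<kind>_metrics.json`` (metrics + agreement +
    provenance) and ``<kind>_predictions.csv``; plus the resolved
    ``config.json`` once.  Returns the in-memory :class:`CVResult` per kind.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config = {
        "hyperparams": hp.to_dict(),
        "folds": folds,
        "seed": seed,
        "model_kinds": list(model_kinds),
        "n_samples": cohort.n_samples,
    }
    prov = provenance(config, seed)
    with open(out / "config.json", "w") as fh:
        json.dump({**config, "provenance": prov}, fh, indent=1, sort_keys=True)

    results: dict[str, CVResult] = {}
    for kind in model_kinds:
        res = kfold_cv(cohort, folds, seed, hp, model_kind=kind)
        results[kind] = res
        report = {
            "model": kind,
            "metrics": res.metrics.to_dict(),
            "agreement": res.agreement.to_dict(),
            "eta_per_fold": [e.tolist() for e in res.eta_per_fold],
            "provenance": prov,
        }
        with open(out / f"{kind}_metrics.json", "w") as fh:
            json.dump(report, fh, indent=1, sort_keys=True)
        pred_path = out / f"{kind}_predictions.csv"
        with open(pred_path, "w") as fh:
            for key, val in prov.items():
                fh.write(f"# {key}={val}\n")
            pd.DataFrame(
                {
                    "prediction": res.predictions,
                    "reference": res.reference,
                    "fold": res.fold_assignment,
                }
            ).to_csv(fh, index=False)
        logger.info(
            "%s: RMSE=%.4f R=%.4f outside=%d/%d",
            kind, res.metrics.rmse, res.metrics.r,
            res.agreement.n_outside, cohort.n_samples,
        )
    return results


def tune_grid(
    cohort: CohortTable,
    base_hp: Hyperparams,
    grid: dict[str, list],
    folds: int,
    seed: int,
    out_csv=None,
    model_kind: str = "mlaprbfn",
) -> pd.DataFrame:
    """Exhaustive grid evaluation of CV RMSE over Hyperparams fields.

    ``grid`` maps field names (``p``, ``tmax``, ``lambda1``, ``lambda2``,
    ...) to candidate lists.  Every cell shares the same CV ``seed``.  A
    failing cell is recorded (``error`` column) and the sweep continues.
    Returns the surface with an ``is_best`` marker on the arg-min RMSE row.
    """
    if not grid:
        raise ValueError("grid must be non-empty")
    names = sorted(grid)
    rows = []
    for combo in itertools.product(*(grid[n] for n in names)):
        settings = dict(zip(names, combo))
        hp = Hyperparams.from_dict({**base_hp.to_dict(), **settings})
        row = dict(settings)
        try:
            res = kfold_cv(cohort, folds, seed, hp, model_kind=model_kind)
            row["rmse"] = res.metrics.rmse
            row["r"] = res.metrics.r
            row["error"] = ""
        except Exception as exc:  # record, keep sweeping
            logger.warning("grid cell %s failed: %s", settings, exc)
            row["rmse"] = float("nan")
            row["r"] = float("nan")
            row["error"] = str(exc)
        rows.append(row)
    surface = pd.DataFrame(rows)
    ok = surface["rmse"].notna()
    surface["is_best"] = False
    if ok.any():
        surface.loc[surface.loc[ok, "rmse"].idxmin(), "is_best"] = True
    if out_csv is not None:
        prov = provenance({"grid": {k: list(v) for k, v in grid.items()},
                           "base": base_hp.to_dict(), "folds": folds}, seed)
        with open(out_csv, "w") as fh:
            for key, val in prov.items():
                fh.write(f"# {key}={val}\n")
            surface.to_csv(fh, index=False)
    return surface
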