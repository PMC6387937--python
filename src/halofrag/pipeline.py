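"""End-to-end library design pipeline with reproducible run manifests.

Stage order: load/generate input -> standardize -> filters (structural,
SMARTS, price) -> distance matrix -> MaxMin core -> satellites ->
assembly (with the consensus solubility vote) -> profile.  Each stage's
output is written before the next starts, and a manifest records the
config hash, input digests, per-stage record counts and every seed, so
identical config + inputs reproduce byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np

from . import __version__
from .chemio import (
    FixtureSpec,
    MoleculeRecord,
    generate_fixtures,
    read_molecules,
    standardize,
    write_molecules,
)
from .config import SimilarityParams, VmaxParams, config_hash
from .descriptors import esol_logs
from .design import (
    PredictionTable,
    assemble_library,
    load_price_table,
    maxmin_select,
    price_filter,
    satellite_select,
    smarts_filter,
    solubility_vote,
    structural_filter,
)
from .profiling import profile_library
from .similarity import distance_matrix
from .vmax import VmaxProvider, VmaxTable

logger = logging.getLogger(__name__)


def synthetic_prediction_table(
    records: list[MoleculeRecord], seed: int, n_predictors: int = 6, sigma: float = 0.5
) -> PredictionTable:
    """Emulate a six-predictor consensus table: the built-in ESOL estimate
    plus deterministic pseudo-predictors (ESOL + seeded Gaussian spread of
    ``sigma`` log units), standing in for the external predictors a real
    run would ingest."""
    rng = np.random.default_rng(seed)
    preds = {}
    for rec in records:
        base = esol_logs(rec)
        values = {"esol": base}
        for k in range(1, n_predictors):
            values[f"synthetic_{k}"] = base + float(rng.normal(0.0, sigma))
        preds[rec.id] = values
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return PredictionTable(preds)


def synthetic_price_table(records: list[MoleculeRecord], seed: int) -> dict[str, float]:
    """Emulate vendor pricing: lognormal $/mg with a realistic tail above
    the $5/mg cap."""
    rng = np.random.default_rng(seed)
    return {rec.id: round(float(np.exp(rng.normal(0.5, 0.9))), 2) for rec in records}


DEFAULT_CONFIG: dict = {
    "input": {"fixtures": {"seed": 0, "count": 300}},
    "tables": {"prices": "synthetic", "predictions": "synthetic", "vmax": None},
    "filters": {"hac_limit": 20, "price_limit": 5.0, "price_missing_policy": "remove"},
    "vote": {"votes_required": 3, "stage": "assembly", "require_pass": False},
    "selection": {"core_size": 20, "n_satellites": 5, "max_total": 40, "seed_id": None},
    "similarity": {},
    "vmax_params": {},
    "profile": {"conformer_seed": 2019, "plots": False, "include_vmax": True},
    "seed": 0,
}


def _merge(defaults: dict, override: dict) -> dict:
    out = {}
    for key, value in defaults.items():
        if key == "input" and key in override:
            out[key] = override[key]  # input source is replaced, not merged
        elif isinstance(value, dict):
            out[key] = _merge(value, override.get(key, {}) or {})
        else:
            out[key] = override.get(key, value)
    for key, value in override.items():
        if key not in defaults:
            out[key] = value
    return out


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _load_input(cfg: dict, digests: dict) -> list[MoleculeRecord]:
    spec = cfg["input"]
    if "fixtures" in spec and spec["fixtures"]:
        fx = spec["fixtures"]
        return generate_fixtures(FixtureSpec(seed=int(fx.get("seed", 0)), count=int(fx.get("count", 300))))
    if "path" in spec and spec["path"]:
        path = Path(spec["path"])
        if not path.exists():
            raise FileNotFoundError(f"config input.path: {path} does not exist")
        digests[str(path)] = _digest(path)
        records, errors = read_molecules(path, spec.get("format"))
        for err in errors:
            logger.warning("input parse error: %s", err.message)
        return records
    raise ValueError("config input must define either 'fixtures' or 'path'")


def run_pipeline(config: dict | None, outdir: str | Path) -> dict:
    """Run the full design pipeline; returns the manifest dict.

    ``config`` overrides :data:`DEFAULT_CONFIG` (nested keys merge).
    Outputs written to ``outdir``: standardized input, filter report,
    distance matrix, selection, library SMILES, profile and manifest.
    """
    cfg = _merge(DEFAULT_CONFIG, config or {})
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    digests: dict[str, str] = {}
    counts: dict[str, int] = {}
    seed = int(cfg["seed"])

    # Stage 1: input + standardization.
    records = [standardize(r) for r in _load_input(cfg, digests)]
    counts["input"] = len(records)
    write_molecules(records, outdir / "standardized.smi")

    # Stage 2: tables.
    tables = cfg["tables"]
    if tables["prices"] == "synthetic":
        prices = synthetic_price_table(records, seed=seed + 11)
    elif tables["prices"]:
        path = Path(tables["prices"])
        if not path.exists():
            raise FileNotFoundError(f"config tables.prices: {path} does not exist")
        digests[str(path)] = _digest(path)
        prices = load_price_table(path)
    else:
        prices = None
    if tables["predictions"] == "synthetic":
        predictions = synthetic_prediction_table(records, seed=seed + 23)
    elif tables["predictions"]:
        path = Path(tables["predictions"])
        if not path.exists():
            raise FileNotFoundError(f"config tables.predictions: {path} does not exist")
        digests[str(path)] = _digest(path)
        predictions = PredictionTable.from_csv(path)
    else:
        predictions = None
    vmax_table = None
    if tables["vmax"]:
        path = Path(tables["vmax"])
        if not path.exists():
            raise FileNotFoundError(f"config tables.vmax: {path} does not exist")
        digests[str(path)] = _digest(path)
        vmax_table = VmaxTable.from_csv(path)

    # Stage 3: filters.
    fcfg = cfg["filters"]
    report = structural_filter(records, hac_limit=int(fcfg["hac_limit"]))
    report = report.merge(smarts_filter(records))
    if prices is not None:
        report = report.merge(
            price_filter(
                records,
                prices,
                limit=float(fcfg["price_limit"]),
                missing_policy=fcfg["price_missing_policy"],
            )
        )

    vcfg = cfg["vote"]
    vote_pass: dict[str, bool] = {}
    if predictions is not None:
        for rec in records:
            if rec.id not in predictions.predictions:
                continue
            hac = rec.mol.GetNumHeavyAtoms()
            if hac > 22:
                vote_pass[rec.id] = False
                continue
            vote_pass[rec.id] = solubility_vote(
                hac, predictions.values_for(rec.id), votes_required=int(vcfg["votes_required"])
            )
        if vcfg["stage"] == "prefilter":
            from .design import FilterReport

            vote_report = FilterReport()
            for rec in records:
                vote_report.add(
                    rec.id, [] if vote_pass.get(rec.id, False) else ["solubility_vote_failed"]
                )
            report = report.merge(vote_report)

    report.to_frame().to_csv(outdir / "filter_report.csv", index=False)
    kept = [r for r in records if report.decisions[r.id].kept]
    counts["after_filters"] = len(kept)
    write_molecules(kept, outdir / "filtered.smi")
    if not kept:
        raise ValueError("no molecules survive filtering; nothing to select from")

    # Stage 4: distance matrix.
    sim_params = SimilarityParams(**cfg["similarity"])
    vmax_params = VmaxParams(**cfg["vmax_params"])
    provider = VmaxProvider(table=vmax_table, params=vmax_params)
    dmat = distance_matrix(kept, sim_params, provider)
    dmat.to_csv(outdir / "distance_matrix.csv")
    counts["distance_matrix_n"] = len(dmat.ids)

    # Stage 5: selection.
    scfg = cfg["selection"]
    seed_id = scfg["seed_id"] or min(dmat.ids)
    core = maxmin_select(dmat, k=int(scfg["core_size"]), seed_id=seed_id)
    counts["core"] = len(core)
    satellites = satellite_select(dmat, core, n_sat=int(scfg["n_satellites"]))
    counts["satellite_candidates"] = len(
        {s for sats in satellites.values() for s in sats}
    )

    # Stage 6: assembly.
    logs = (
        {rec.id: predictions.consensus_logs(rec.id) for rec in kept if rec.id in predictions.predictions}
        if predictions is not None
        else {}
    )
    result = assemble_library(
        core,
        satellites,
        max_total=int(scfg["max_total"]),
        vote_pass=vote_pass,
        logs=logs,
        prices=prices or {},
        require_vote_pass=bool(vcfg["require_pass"]),
    )
    counts["final"] = len(result.final_ids)
    by_id = {r.id: r for r in kept}
    library = [by_id[i] for i in result.final_ids]
    write_molecules(library, outdir / "library.smi")
    with open(outdir / "selection.json", "w") as fh:
        json.dump(result.to_json_payload(), fh, indent=2, sort_keys=True)
        fh.write("\n")

    # Stage 7: profile.
    pcfg = cfg["profile"]
    profile = profile_library(
        library,
        conformer_seed=int(pcfg["conformer_seed"]),
        vmax_provider=provider if pcfg["include_vmax"] else None,
    )
    profile.write_json(outdir / "profile.json")
    if pcfg["plots"]:
        from .profiling import plot_profile

        plot_profile(profile, outdir / "plots")

    manifest = {
        "package_version": __version__,
        "config": cfg,
        "config_hash": config_hash(cfg),
        "input_digests": digests,
        "stage_counts": counts,
        "seeds": {
            "pipeline": seed,
            "fixtures": cfg["input"].get("fixtures", {}).get("seed"),
            "conformer": int(pcfg["conformer_seed"]),
        },
        "param_hashes": {
            "similarity": sim_params.param_hash(),
            "vmax": vmax_params.param_hash(),
        },
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    logger.info("pipeline finished: %s", counts)
    return manifest
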