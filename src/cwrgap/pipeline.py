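"""Pipeline stages over on-disk artifacts.

Each stage reads delimited-text inputs, runs the corresponding library
operations and writes delimited-text / JSON outputs plus a run manifest
(config echo, seeds, package version, input checksums), so stages are
individually invokable and chainable.  The CLI in :mod:`cwrgap.cli` is a
thin wrapper over these functions.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd

from . import __version__
from .grid import GridSpec
from .occurrences import clean_occurrences, dedupe_cells, is_modellable, read_occurrences, thin_cells
from .passport import CollectedConfig, country_gaps, native_collected_counts, parse_passport, summarize
from .priority import RuleConfig, build_priority_table
from .range_change import SCENARIOS, build_table
from .rasters import EnvStack
from .registry import load_registry
from .sdm import EnsembleConfig, EnsembleSDM
from .synthetic import LayerSpec, NicheSpec, make_env_stack, make_passport_file, simulate_occurrences

logger = logging.getLogger(__name__)


class DependencyError(RuntimeError):
    """A required upstream artifact is missing."""


def _sha256(path: Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_manifest(outdir: Path, stage: str, config: dict, inputs: list) -> Path:
    manifest = {
        "stage": stage,
        "version": __version__,
        "config": config,
        "inputs": {str(p): _sha256(p) for p in inputs if Path(p).is_file()},
    }
    path = Path(outdir) / f"{stage}_manifest.json"
    path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return path


# -- gap report -------------------------------------------------------------


def run_gap_report(
    registry_path,
    passport_path,
    outdir,
    thresholds: tuple = (10, 20),
    collected: CollectedConfig | None = None,
) -> dict:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    registry = load_registry(registry_path)
    records = parse_passport(passport_path)
    stats = native_collected_counts(records, registry, collected)
    rows = []
    for taxon in registry:
        entry = stats.get(taxon.canonical_name)
        gaps = country_gaps(entry, registry) if entry else set(taxon.native_countries)
        rows.append(
            {
                "taxon": taxon.canonical_name,
                "tier": taxon.tier,
                "total_accessions": entry.total_accessions if entry else 0,
                "native_collected": entry.native_collected if entry else 0,
                "n_native_countries": len(taxon.native_countries),
                "n_gap_countries": len(gaps),
                "gap_countries": "|".join(sorted(gaps)),
            }
        )
    pd.DataFrame(rows).to_csv(outdir / "taxon_stats.tsv", sep="\t", index=False)
    summary = summarize(stats, registry, thresholds)
    report = {
        "n_taxa": registry.n_taxa,
        "n_genera": registry.n_genera,
        "grand_total": summary.grand_total,
        "totals_by_tier": summary.totals_by_tier,
        "native_collected_total": summary.native_collected_total,
        "tertiary_fraction_below": {str(k): v for k, v in summary.tertiary_fraction_below.items()},
        "n_records": len(records),
    }
    (outdir / "gap_report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    write_manifest(outdir, "gap-report", {"thresholds": list(thresholds)}, [registry_path, passport_path])
    logger.info("gap-report: %d records over %d taxa", len(records), registry.n_taxa)
    return report


# -- sdm --------------------------------------------------------------------


def _write_cells(path: Path, taxon: str, cells, grid: GridSpec) -> None:
    rows = []
    for row, col in sorted(cells):
        lon, lat = grid.cell_center((row, col))
        rows.append({"taxon": taxon, "row": row, "col": col, "lon_center": lon, "lat_center": lat})
    pd.DataFrame(rows, columns=["taxon", "row", "col", "lon_center", "lat_center"]).to_csv(
        path, sep="\t", index=False
    )


def read_cells(path) -> set:
    df = pd.read_csv(path, sep="\t")
    return {(int(r), int(c)) for r, c in zip(df["row"], df["col"])}


def run_sdm(
    occurrences_path,
    env_current_dir,
    env_future_dirs: dict,
    outdir,
    seed: int = 0,
    taxon: str | None = None,
    min_cells: int = 10,
    region: tuple | None = None,
    sdm_config: EnsembleConfig | None = None,
) -> dict:
    """Fit the ensemble for one taxon's occurrences and project it.

    ``env_future_dirs`` maps scenario name -> directory of future-layer
    ASCII grids.  Writes projected cell sets (current + per scenario),
    the model manifest, and a processing log of dropped records/cells.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    env = EnvStack.from_files(sorted(Path(env_current_dir).glob("*.asc")))
    futures = {
        scenario: EnvStack.from_files(sorted(Path(d).glob("*.asc")))
        for scenario, d in env_future_dirs.items()
    }
    raw = read_occurrences(occurrences_path)
    if taxon is not None:
        raw = raw[raw["taxon_name"] == taxon]
    name = taxon or (raw["taxon_name"].iloc[0] if len(raw) else "unknown")
    cleaned, rejected = clean_occurrences(raw, region)
    cells = dedupe_cells(cleaned, env.grid)
    thinned = thin_cells(cells)
    log = {
        "taxon": name,
        "n_records": int(len(raw)),
        "n_rejected": len(rejected),
        "n_cells": len(cells),
        "n_thinned": len(thinned),
    }
    if not is_modellable(thinned, min_cells):
        log["modellable"] = False
        (outdir / "sdm_log.json").write_text(json.dumps(log, indent=1))
        raise ValueError(
            f"insufficient occurrence cells for {name!r}: "
            f"{len(thinned)} after thinning, {min_cells} required"
        )
    model = EnsembleSDM(thinned, env, sdm_config)
    results = model.fit(seed)
    _, current_cells = results.project(env)
    _write_cells(outdir / "projection_current.tsv", name, current_cells, env.grid)
    for scenario, fenv in futures.items():
        _, future_cells = results.project(fenv)
        tag = scenario.replace(".", "")
        _write_cells(outdir / f"projection_{tag}.tsv", name, future_cells, env.grid)
    log["modellable"] = True
    log["members"] = results.to_manifest()["members"]
    (outdir / "sdm_log.json").write_text(json.dumps(log, indent=1))
    (outdir / "model_manifest.json").write_text(json.dumps(results.to_manifest(), indent=1))
    write_manifest(outdir, "sdm", {"seed": seed, "min_cells": min_cells}, [occurrences_path])
    return log


# -- range change -----------------------------------------------------------


def run_range_change(projections_dir, outdir, reasons: dict | None = None) -> Path:
    """Build the range-change table from projection artifacts.

    Expects ``projection_current.tsv`` and ``projection_<scenario>.tsv``
    per taxon directory under ``projections_dir`` (one subdirectory per
    taxon, or a single taxon's files directly).
    """
    projections_dir = Path(projections_dir)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    taxon_dirs = [d for d in sorted(projections_dir.iterdir()) if d.is_dir()]
    if not taxon_dirs and (projections_dir / "projection_current.tsv").is_file():
        taxon_dirs = [projections_dir]
    projections: dict = {}
    for d in taxon_dirs:
        current = d / "projection_current.tsv"
        if not current.is_file():
            continue
        df = pd.read_csv(current, sep="\t")
        name = df["taxon"].iloc[0] if len(df) else d.name
        entry = {"current": read_cells(current)}
        for scenario in SCENARIOS:
            f = d / f"projection_{scenario.replace('.', '')}.tsv"
            if f.is_file():
                entry[scenario] = read_cells(f)
        projections[name] = entry
    if not projections:
        raise DependencyError(
            f"no projection artifacts under {projections_dir}; run the 'sdm' stage first"
        )
    for taxon, reason in (reasons or {}).items():
        projections.setdefault(taxon, reason)
    records = build_table(projections)
    rows = []
    for r in records:
        rows.append(
            {
                "taxon": r.taxon,
                "current_size": r.current_size if r.current_size is not None else "",
                "mig_rcp26": r.change_mig.get("RCP2.6", ""),
                "mig_rcp85": r.change_mig.get("RCP8.5", ""),
                "nomig_rcp26": r.change_nomig.get("RCP2.6", ""),
                "nomig_rcp85": r.change_nomig.get("RCP8.5", ""),
                "reason": r.reason or "",
            }
        )
    out = outdir / "range_change.tsv"
    pd.DataFrame(rows).to_csv(out, sep="\t", index=False)
    write_manifest(outdir, "range-change", {}, [])
    return out


# -- priority ---------------------------------------------------------------


def run_priority(
    registry_path, stats_path, range_table_path, outdir, rules: RuleConfig | None = None
) -> dict:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for path, stage in [(stats_path, "gap-report"), (range_table_path, "range-change")]:
        if not Path(path).is_file():
            raise DependencyError(f"missing artifact {path}; run the '{stage}' stage first")
    registry = load_registry(registry_path)
    stats_df = pd.read_csv(stats_path, sep="\t")
    from .passport import TaxonStats

    stats = {
        row["taxon"]: TaxonStats(
            canonical_name=row["taxon"],
            total_accessions=int(row["total_accessions"]),
            native_collected=int(row["native_collected"]),
        )
        for _, row in stats_df.iterrows()
    }
    range_df = pd.read_csv(range_table_path, sep="\t")
    from .range_change import RangeChangeRecord

    range_records = []
    for _, row in range_df.iterrows():
        if pd.isna(row["current_size"]) or row["current_size"] == "":
            range_records.append(RangeChangeRecord(taxon=row["taxon"], reason=str(row.get("reason") or "")))
        else:
            range_records.append(
                RangeChangeRecord(
                    taxon=row["taxon"],
                    current_size=int(row["current_size"]),
                    change_mig={"RCP2.6": float(row["mig_rcp26"]), "RCP8.5": float(row["mig_rcp85"])},
                    change_nomig={"RCP2.6": float(row["nomig_rcp26"]), "RCP8.5": float(row["nomig_rcp85"])},
                )
            )
    rules = rules or RuleConfig()
    assignments = build_priority_table(registry, stats, range_records, rules)
    pd.DataFrame(
        [{"taxon": a.taxon, "category": a.category, "rule_fired": a.rule_fired} for a in assignments]
    ).to_csv(outdir / "priority.tsv", sep="\t", index=False)
    counts: dict[str, int] = {}
    for a in assignments:
        counts[a.category] = counts.get(a.category, 0) + 1
    rules_manifest = {
        "redlist_high": sorted(rules.redlist_high),
        "acc_floor_high": rules.acc_floor_high,
        "loss_high": rules.loss_high,
        "acc_cap_for_loss_rule": rules.acc_cap_for_loss_rule,
        "acc_low": rules.acc_low,
        "exclusions": sorted(rules.exclusions),
        "category_counts": counts,
    }
    (outdir / "priority_rules.json").write_text(json.dumps(rules_manifest, indent=1))
    write_manifest(outdir, "priority", rules_manifest, [registry_path, stats_path, range_table_path])
    return counts


# -- simulate ---------------------------------------------------------------


def run_simulate(spec: dict, outdir, seed: int = 0) -> dict:
    """Generate a self-contained synthetic input set from a spec mapping.

    Spec keys: ``grid`` (GridSpec fields), ``layers`` (LayerSpec fields),
    ``niche`` (bounds or gaussian), ``shifts`` (scenario -> layer deltas),
    ``n_draws``, optional ``passport``/``registry``.
    Writes current/future ASCII-grid directories, an occurrence table, a
    registry and optionally a passport file; returns the artifact paths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    grid = GridSpec(**spec["grid"])
    layer_specs = [LayerSpec(**ls) for ls in spec["layers"]]
    current, _ = make_env_stack(grid, layer_specs, None, seed)
    env_current = outdir / "env_current"
    current.to_dir(env_current)
    paths = {"env_current": str(env_current), "env_future": {}}
    for scenario, deltas in spec.get("shifts", {}).items():
        future = current.shifted(deltas)
        d = outdir / f"env_{scenario.replace('.', '')}"
        future.to_dir(d)
        paths["env_future"][scenario] = str(d)
    niche_spec = spec["niche"]
    niche = NicheSpec(
        bounds={k: tuple(v) for k, v in niche_spec["bounds"].items()} if "bounds" in niche_spec else None,
        gaussian={k: tuple(v) for k, v in niche_spec["gaussian"].items()} if "gaussian" in niche_spec else None,
    )
    records, truth = simulate_occurrences(
        niche, current, n_draws=int(spec.get("n_draws", 300)), seed=seed,
        mode=spec.get("mode", "uniform"),
    )
    taxon = spec.get("taxon_name", "Synthetica exempli L.")
    records["taxon_name"] = taxon
    occ_path = outdir / "occurrences.tsv"
    records.rename(columns={"taxon_name": "species"}).to_csv(occ_path, sep="\t", index=False)
    paths["occurrences"] = str(occ_path)
    truth_path = outdir / "occurrences.truth.tsv"
    _write_cells(truth_path, taxon, truth, grid)
    if "registry" in spec:
        reg_path = outdir / "registry.tsv"
        pd.DataFrame(spec["registry"]).to_csv(reg_path, sep="\t", index=False)
        paths["registry"] = str(reg_path)
    if "passport" in spec:
        pp_path, _ = make_passport_file(spec["passport"], outdir / "passport.tsv", seed)
        paths["passport"] = str(pp_path)
    write_manifest(outdir, "simulate", {"seed": seed, "taxon": taxon}, [])
    return paths


# -- all --------------------------------------------------------------------


def run_all(config: dict, outdir=None, seed: int | None = None) -> dict:
    """Run the full chain: simulate (optional) -> gap-report -> sdm ->
    range-change -> priority.  Returns the stage summaries."""
    outdir = Path(outdir or config.get("outdir", "cwrgap_out"))
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0) if seed is None else seed)
    results: dict = {}
    paths = dict(config.get("paths", {}))
    if "simulate" in config:
        sim = run_simulate(config["simulate"], outdir / "inputs", seed)
        paths = {**sim, **paths}
    for key in ("registry", "passport", "occurrences", "env_current"):
        if key not in paths:
            raise KeyError(f"config missing path {key!r}")
    results["gap_report"] = run_gap_report(
        paths["registry"], paths["passport"], outdir / "gap_report"
    )
    sdm_cfg = EnsembleConfig(**config.get("sdm", {}))
    taxon = config.get("simulate", {}).get("taxon_name", config.get("taxon"))
    sdm_dir = outdir / "sdm" / "taxon_1"
    results["sdm"] = run_sdm(
        paths["occurrences"],
        paths["env_current"],
        paths.get("env_future", {}),
        sdm_dir,
        seed=seed,
        taxon=taxon,
        min_cells=int(config.get("min_cells", 10)),
        sdm_config=sdm_cfg,
    )
    range_table = run_range_change(outdir / "sdm", outdir / "range_change")
    results["range_change"] = str(range_table)
    rules_cfg = config.get("rules", {})
    rules = RuleConfig(
        **{
            **rules_cfg,
            **(
                {"exclusions": frozenset(rules_cfg["exclusions"])}
                if "exclusions" in rules_cfg
                else {}
            ),
        }
    )
    results["priority"] = run_priority(
        paths["registry"],
        outdir / "gap_report" / "taxon_stats.tsv",
        range_table,
        outdir / "priority",
        rules,
    )
    write_manifest(outdir, "all", {"seed": seed, "config": {k: str(v) for k, v in paths.items()}}, [])
    return results
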