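"""Synthetic landscapes, occurrences and passport files with known truth.

Every pipeline stage can be exercised without any external download:

* :func:`make_env_stack` builds smooth gradient-plus-noise environmental
  layers on a grid, optionally together with a "future" twin shifted by
  a prescribed per-layer delta (emulating scenario warming);
* :func:`simulate_occurrences` draws presence records from a parametric
  climate niche over such a stack, recording the truly suitable cell set
  as ground truth;
* :func:`expected_range_change` evaluates the niche analytically under
  the current and shifted stacks — the oracle for the range-change
  metrics;
* :func:`make_passport_file` writes an MCPD passport table with known
  per-taxon / per-country / per-status counts, saved alongside as a
  ground-truth tally.

Two niche truth modes are supported: hard envelope bounds (exact
oracles) and Gaussian suitability (realistic misspecification).  All
generators are pure functions of (spec, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .grid import CellSet, GridSpec
from .range_change import change_no_migration, change_with_migration
from .rasters import EnvStack

__all__ = [
    "LayerSpec",
    "NicheSpec",
    "ClimateShift",
    "make_env_stack",
    "simulate_occurrences",
    "true_suitable_cells",
    "expected_range_change",
    "make_passport_file",
]


@dataclass(frozen=True)
class LayerSpec:
    """Recipe for one synthetic environmental layer.

    The deterministic part is a linear gradient from ``low`` to ``high``
    along rows or columns; optional Gaussian noise and value quantization
    are applied on top.  Quantization (e.g. to 0.5-unit steps) mimics the
    discretized values of distributed climate grids and ensures extreme
    values are shared by many cells.
    """

    name: str
    gradient: str = "col"  # "col" | "row"
    low: float = 0.0
    high: float = 1.0
    noise_sd: float = 0.0
    quantize: float | None = None


@dataclass(frozen=True)
class NicheSpec:
    """Parametric climate niche.

    ``bounds`` (hard envelope truth): layer name -> (lower, upper); a
    cell is suitable iff every bounded layer lies inside its interval.
    ``gaussian`` (smooth truth): layer name -> (optimum, tolerance); the
    suitability is the product of Gaussian kernels and a cell is
    suitable where it exceeds ``threshold``.
    """

    bounds: dict | None = None
    gaussian: dict | None = None
    threshold: float = 0.5
    max_prevalence: float = 1.0

    def __post_init__(self) -> None:
        if (self.bounds is None) == (self.gaussian is None):
            raise ValueError("specify exactly one of bounds / gaussian")
        if self.bounds:
            for name, (lo, hi) in self.bounds.items():
                if not lo <= hi:
                    raise ValueError(f"bounds for {name!r} not well-ordered")
        if self.gaussian:
            for name, (_, tol) in self.gaussian.items():
                if tol <= 0:
                    raise ValueError(f"tolerance for {name!r} must be positive")

    def suitability(self, env: EnvStack) -> np.ndarray:
        """Cell-wise suitability in [0, 1] (NaN where masked)."""
        if self.bounds is not None:
            ok = np.ones(env.grid.shape, dtype=float)
            for name, (lo, hi) in self.bounds.items():
                layer = env.layer(name)
                ok *= ((layer >= lo) & (layer <= hi)).astype(float)
            out = ok
        else:
            out = np.ones(env.grid.shape, dtype=float)
            for name, (opt, tol) in self.gaussian.items():
                layer = env.layer(name)
                out *= np.exp(-0.5 * ((layer - opt) / tol) ** 2)
        out = np.where(env.mask, out, np.nan)
        return out


@dataclass(frozen=True)
class ClimateShift:
    """Per-layer additive deltas applied to build the future stack."""

    deltas: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, delta in self.deltas.items():
            if not np.isfinite(delta):
                raise ValueError(f"non-finite shift for layer {name!r}")


def make_env_stack(
    grid: GridSpec,
    layer_specs: list[LayerSpec],
    shift: ClimateShift | None = None,
    seed: int = 0,
) -> tuple[EnvStack, EnvStack | None]:
    """Build a current stack (and its shifted future twin) from recipes."""
    rng = np.random.default_rng(seed)
    layers = {}
    for spec in layer_specs:
        if spec.gradient == "col":
            base = np.linspace(spec.low, spec.high, grid.n_cols)
            data = np.tile(base, (grid.n_rows, 1))
        elif spec.gradient == "row":
            base = np.linspace(spec.low, spec.high, grid.n_rows)
            data = np.tile(base[:, None], (1, grid.n_cols))
        else:
            raise ValueError(f"unknown gradient {spec.gradient!r}")
        if spec.noise_sd > 0:
            data = data + rng.normal(0.0, spec.noise_sd, size=grid.shape)
        if spec.quantize:
            data = np.round(data / spec.quantize) * spec.quantize
        layers[spec.name] = data
    current = EnvStack(grid, layers)
    future = current.shifted(shift.deltas) if shift is not None else None
    return current, future


def true_suitable_cells(niche: NicheSpec, env: EnvStack) -> CellSet:
    """Cells whose true suitability reaches the niche threshold."""
    suit = niche.suitability(env)
    cut = niche.threshold if niche.gaussian is not None else 0.5
    rows, cols = np.nonzero(np.nan_to_num(suit, nan=0.0) >= cut)
    return set(zip(rows.tolist(), cols.tolist()))


def simulate_occurrences(
    niche: NicheSpec,
    env: EnvStack,
    n_draws: int = 100,
    seed: int = 0,
    mode: str = "uniform",
) -> tuple[pd.DataFrame, CellSet]:
    """Draw presence records from the niche over the stack.

    Modes: ``uniform`` — ``n_draws`` suitable cells uniformly without
    replacement (all of them if fewer exist); ``exhaustive`` — every
    suitable cell once (noiseless); ``bernoulli`` — each valid cell
    keeps a presence with probability suitability * max_prevalence.
    Returns a Darwin-Core-style frame (taxon_name, decimalLongitude,
    decimalLatitude at cell centres) and the true suitable cell set.
    """
    rng = np.random.default_rng(seed)
    truth = true_suitable_cells(niche, env)
    if mode == "exhaustive":
        chosen = sorted(truth)
    elif mode == "uniform":
        pool = sorted(truth)
        n = min(n_draws, len(pool))
        idx = rng.choice(len(pool), size=n, replace=False) if pool else []
        chosen = [pool[i] for i in idx]
    elif mode == "bernoulli":
        suit = np.nan_to_num(niche.suitability(env), nan=0.0)
        draw = rng.random(env.grid.shape) < suit * niche.max_prevalence
        rows, cols = np.nonzero(draw)
        chosen = list(zip(rows.tolist(), cols.tolist()))
    else:
        raise ValueError(f"unknown sampling mode {mode!r}")
    lons, lats = [], []
    for cell in chosen:
        lon, lat = env.grid.cell_center(cell)
        lons.append(lon)
        lats.append(lat)
    records = pd.DataFrame(
        {
            "taxon_name": "Synthetic taxon",
            "decimalLongitude": lons,
            "decimalLatitude": lats,
        }
    )
    return records, truth


def expected_range_change(
    niche: NicheSpec, env: EnvStack, shift: ClimateShift
) -> tuple[float, float]:
    """Analytic (with-migration, no-migration) percent change.

    Evaluates the niche truth directly on the current and shifted stacks
    — the oracle against which the fitted pipeline is checked.
    """
    current = true_suitable_cells(niche, env)
    future = true_suitable_cells(niche, env.shifted(shift.deltas))
    return (
        change_with_migration(current, future),
        change_no_migration(current, future),
    )


def make_passport_file(
    spec: dict,
    path,
    seed: int = 0,
) -> tuple[Path, dict]:
    """Write an MCPD passport table with prescribed counts.

    ``spec`` maps a taxon label (any name the registry can resolve;
    "Genus species [authority]") to a list of batches
    ``{"origcty": code-or-"", "n": count, "collsrc": int-or-None,
    "sampstat": int-or-None}``.  Rows are emitted in shuffled order
    (seeded) to exercise order independence.  The ground-truth tally
    (per-taxon totals and per-country collected counts under the default
    MCPD code sets) is written next to the file as JSON and returned.
    """
    from .passport import CollectedConfig, PassportRecord

    config = CollectedConfig()
    rows = []
    truth: dict[str, dict] = {}
    counter = 0
    for taxon_label, batches in spec.items():
        parts = taxon_label.split()
        genus, species = parts[0], parts[1] if len(parts) > 1 else ""
        spauthor = " ".join(parts[2:])
        entry = truth.setdefault(
            taxon_label, {"total": 0, "collected_by_country": {}}
        )
        for batch in batches:
            for _ in range(int(batch["n"])):
                counter += 1
                collsrc = batch.get("collsrc")
                sampstat = batch.get("sampstat")
                origcty = batch.get("origcty", "") or ""
                rows.append(
                    {
                        "INSTCODE": "SYN001",
                        "ACCENUMB": f"SYN{counter:06d}",
                        "GENUS": genus,
                        "SPECIES": species,
                        "SPAUTHOR": spauthor,
                        "SUBTAXA": "",
                        "ORIGCTY": origcty,
                        "COLLSRC": "" if collsrc is None else collsrc,
                        "SAMPSTAT": "" if sampstat is None else sampstat,
                    }
                )
                entry["total"] += 1
                record = PassportRecord(
                    accenumb="x", origcty=origcty, collsrc=collsrc, sampstat=sampstat
                )
                if origcty and config.qualifies(record):
                    by_country = entry["collected_by_country"]
                    by_country[origcty] = by_country.get(origcty, 0) + 1
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(rows)) if rows else []
    df = pd.DataFrame([rows[i] for i in order], columns=[
        "INSTCODE", "ACCENUMB", "GENUS", "SPECIES", "SPAUTHOR",
        "SUBTAXA", "ORIGCTY", "COLLSRC", "SAMPSTAT",
    ])
    path = Path(path)
    df.to_csv(path, sep="\t", index=False)
    truth_path = path.with_suffix(path.suffix + ".truth.json")
    truth_path.write_text(json.dumps(truth, indent=1))
    return path, truth
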