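"""Readers and writers for the pipeline's interface files.

Tabular outputs are TSV with ``#`` header comments carrying the tool version
and a hash of the run configuration, so every artifact records its
provenance.  Writes are atomic (temp file + rename).
"""

from __future__ import annotations

import csv
import hashlib
import json
import os
import shutil
import tempfile
from pathlib import Path

import numpy as np
import yaml

import osmoflux
from osmoflux.fitting import FitResult, ConfidenceIntervals, RateMeasurement
from osmoflux.labeling import FluxVector, MassIsotopomerDistribution
from osmoflux.physiology import GrowthTimecourse

KNOWN_CONFIG_KEYS = {
    "seed",
    "restarts",
    "n_monte_carlo",
    "sigma_floor",
    "xi_max",
    "ftol",
    "xtol",
    "condition",
    "mid_sd",
    "rate_rel_sd",
    "tracers",
}


def config_hash(config: dict) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def load_config(path: str | Path) -> dict:
    with Path(path).open() as fh:
        config = yaml.safe_load(fh) or {}
    unknown = set(config) - KNOWN_CONFIG_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return config


def _atomic_write(path: Path, text: str) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def _header(config: dict | None) -> str:
    h = f"# osmoflux {osmoflux.__version__}"
    if config is not None:
        h += f" config_hash={config_hash(config)}"
    return h + "\n"


def write_mid_table(
    path: str | Path,
    mids: list[MassIsotopomerDistribution],
    config: dict | None = None,
) -> None:
    lines = [_header(config), "fragment_id\tmass_shift\tfraction\tsd\n"]
    for mid in mids:
        sd = mid.sd if mid.sd is not None else [np.nan] * len(mid.m)
        for shift, (frac, s) in enumerate(zip(mid.m, sd)):
            lines.append(f"{mid.fragment_id}\t{shift}\t{frac:.10g}\t{s:.6g}\n")
    _atomic_write(Path(path), "".join(lines))


def read_mid_table(path: str | Path) -> list[MassIsotopomerDistribution]:
    rows: dict[str, list[tuple[int, float, float]]] = {}
    with Path(path).open() as fh:
        reader = csv.DictReader(
            (line for line in fh if not line.startswith("#")), delimiter="\t"
        )
        for row in reader:
            rows.setdefault(row["fragment_id"], []).append(
                (int(row["mass_shift"]), float(row["fraction"]), float(row["sd"]))
            )
    mids = []
    for fid, entries in rows.items():
        entries.sort()
        m = np.array([e[1] for e in entries])
        sd = np.array([e[2] for e in entries])
        mids.append(
            MassIsotopomerDistribution(
                fid, m, None if np.all(np.isnan(sd)) else sd, normalized=False
            )
        )
    return mids


def write_rate_table(
    path: str | Path, rates: list[RateMeasurement], config: dict | None = None
) -> None:
    lines = [_header(config), "reaction_id\tvalue\tsd\n"]
    for r in rates:
        lines.append(f"{r.reaction_id}\t{r.value:.10g}\t{r.sd:.6g}\n")
    _atomic_write(Path(path), "".join(lines))


def read_rate_table(path: str | Path) -> list[RateMeasurement]:
    rates = []
    with Path(path).open() as fh:
        reader = csv.DictReader(
            (line for line in fh if not line.startswith("#")), delimiter="\t"
        )
        for row in reader:
            rates.append(
                RateMeasurement(row["reaction_id"], float(row["value"]), float(row["sd"]))
            )
    return rates


def write_flux_table(
    path: str | Path,
    fluxes: FluxVector,
    ci: ConfidenceIntervals | None = None,
    config: dict | None = None,
) -> None:
    """Flux result TSV: reaction, net, exchange, and optional 95 % CI bounds."""
    lines = [_header(config), "reaction_id\tnet\texchange\tci_lo\tci_hi\n"]
    for rid in fluxes.net:
        lo = hi = ""
        if ci is not None and rid in ci.intervals:
            lo, hi = (f"{x:.6g}" for x in ci.intervals[rid])
        lines.append(
            f"{rid}\t{fluxes.net[rid]:.10g}\t{fluxes.exchange.get(rid, 0.0):.10g}"
            f"\t{lo}\t{hi}\n"
        )
    _atomic_write(Path(path), "".join(lines))


def write_flux_map_export(path: str | Path, fluxes: FluxVector) -> None:
    """Two-column (reaction, flux) table for network-visualization tools."""
    lines = ["reaction\tflux\n"]
    for rid, v in fluxes.net.items():
        lines.append(f"{rid}\t{v:.6g}\n")
    _atomic_write(Path(path), "".join(lines))


def read_flux_json(path: str | Path) -> FluxVector:
    with Path(path).open() as fh:
        data = json.load(fh)
    return FluxVector(net=data["net"], exchange=data.get("exchange", {}))


def write_flux_json(path: str | Path, fluxes: FluxVector) -> None:
    _atomic_write(
        Path(path),
        json.dumps({"net": fluxes.net, "exchange": fluxes.exchange}, indent=1),
    )


def write_fit_report(
    path: str | Path, fit: FitResult, config: dict | None = None
) -> None:
    report = {
        "version": osmoflux.__version__,
        "config_hash": config_hash(config or {}),
        "ssr": fit.ssr,
        "dof": fit.dof,
        "seed": fit.seed,
        "n_measurements": fit.problem.n_measurements,
        "n_parameters": fit.problem.n_parameters,
        "free_fluxes": fit.problem.basis.free_ids,
        "restarts": fit.restart_table,
        "nonidentifiable_directions": fit.nonidentifiable,
        "net_fluxes": fit.fluxes.net,
        "exchange_fluxes": fit.fluxes.exchange,
    }
    _atomic_write(Path(path), json.dumps(report, indent=1, default=float))


def write_timecourse(path: str | Path, tc: GrowthTimecourse) -> None:
    cols = ["time_h", "biomass", "glucose_mM"] + [
        f"{name}_mM" for name in tc.products
    ]
    lines = [",".join(cols) + "\n"]
    for i in range(len(tc.time)):
        vals = [tc.time[i], tc.biomass[i], tc.glucose[i]] + [
            tc.products[n][i] for n in tc.products
        ]
        lines.append(",".join(f"{v:.8g}" for v in vals) + "\n")
    _atomic_write(Path(path), "".join(lines))


def read_timecourse(path: str | Path, condition: float = 0.0) -> GrowthTimecourse:
    with Path(path).open(newline="") as fh:
        rows = list(csv.DictReader(fh))
    time = np.array([float(r["time_h"]) for r in rows])
    biomass = np.array([float(r["biomass"]) for r in rows])
    glucose = np.array([float(r["glucose_mM"]) for r in rows])
    products = {}
    for col in rows[0]:
        if col.endswith("_mM") and col != "glucose_mM":
            products[col[:-3]] = np.array([float(r[col]) for r in rows])
    return GrowthTimecourse(time, biomass, glucose, products, condition)


def write_bundle(
    out_dir: str | Path,
    scenario,
    experiments: list,
    config: dict,
) -> Path:
    """Write a complete synthetic problem bundle directory.

    Contents: the model CSV, one MID TSV and one rate TSV per tracer, the
    biomass composition CSV, the run config, and truth.json with the hidden
    ground-truth flux vector.
    """
    from osmoflux.model import shipped_biomass_path, shipped_model_path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    shutil.copy(shipped_model_path(), out / "model.csv")
    shutil.copy(shipped_biomass_path(), out / "biomass.csv")
    tracer_names = []
    for tracer, raws, rates in experiments:
        fully = any(
            set(p) == {"1"} and abs(f - 0.5) < 1e-9 for p, f in tracer.species
        )
        name = "U-50" if fully else "1-13C"
        tracer_names.append(name)
        write_mid_table(out / f"mids_{name}.tsv", raws, config)
        write_rate_table(out / f"rates_{name}.tsv", rates, config)
    config = dict(config, tracers=tracer_names)
    _atomic_write(out / "config.yaml", yaml.safe_dump(config))
    _atomic_write(
        out / "truth.json",
        json.dumps(
            {
                "net": scenario.true_fluxes.net,
                "exchange": scenario.true_fluxes.exchange,
                "fixed": scenario.fixed,
                "condition": scenario.condition,
            },
            indent=1,
        ),
    )
    return out
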