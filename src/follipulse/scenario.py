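"""YAML scenario runner: simulate every requested module, analyze, write reports.

A scenario file names the simulation blocks to run (volume cohorts, AFM
regions, mechano records, expression matrix, recoil groups, UTR set), a global
seed, and optional per-block parameter overrides.  ``run_scenario`` derives
one child seed per block from the global seed, simulates, runs the matching
analysis, and writes CSV inputs, a ``report.json`` of results and a
``manifest.json`` recording version, seeds and parameters.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import yaml

from . import __version__, actin, afm, io as fio, mechano, recoil as rc, synth, volume as vol
from .errors import ConfigError

_MODULE_ORDER = ("volume", "afm", "mechano", "expression", "recoil", "targets")
_TOP_KEYS = {"name", "seed", *_MODULE_ORDER}


def load_scenario(path) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ConfigError("scenario file must contain a mapping")
    unknown = set(data) - _TOP_KEYS
    if unknown:
        raise ConfigError(
            f"unknown scenario keys {sorted(unknown)}; valid keys: {sorted(_TOP_KEYS)}"
        )
    return data


def _child_seeds(seed: int) -> dict[str, int]:
    children = np.random.SeedSequence(seed).spawn(len(_MODULE_ORDER))
    return {
        name: int(child.generate_state(1)[0] % (2**31))
        for name, child in zip(_MODULE_ORDER, children)
    }


def _params_with(cls, overrides: dict, seed: int):
    valid = {f.name for f in dataclasses.fields(cls)}
    unknown = set(overrides) - valid
    if unknown:
        raise ConfigError(
            f"unknown {cls.__name__} keys {sorted(unknown)}; valid keys: {sorted(valid)}"
        )
    clean = {
        k: tuple(v) if isinstance(v, list) else v for k, v in overrides.items()
    }
    return cls(**{**clean, "seed": seed})


def _run_volume(block: dict, seed: int, out: Path) -> dict:
    report: dict = {"cohorts": {}}
    fractions: dict[str, float] = {}
    for idx, (cohort_name, cfg) in enumerate(sorted(block.items())):
        cfg = dict(cfg or {})
        preset = cfg.pop("preset", "telogen")
        layout = cfg.pop("layout", None)
        base = synth.anagen_params if preset == "anagen" else synth.telogen_params
        if preset not in ("telogen", "anagen"):
            raise ConfigError(f"unknown volume preset {preset!r}; use telogen or anagen")
        params = base(seed=seed + idx, **{
            k: tuple(v) if isinstance(v, list) else v for k, v in cfg.items()
        })
        counts = synth.cohort_point_counts(params.stage) if layout == "paper" else None
        if counts is not None:
            params = dataclasses.replace(params, n_follicles=len(counts))
        trajs, truth = synth.gen_volume_trajectories(params, counts)
        fio.write_trajectories(trajs, out / f"volume_{cohort_name}.csv")
        rels = [vol.normalize_trajectory(t) for t in trajs]
        calls = [vol.classify_behavior(r) for r in rels]
        frac = vol.contraction_fraction(rels)
        accuracy = float(np.mean([c.category == t for c, t in zip(calls, truth)]))
        fractions[cohort_name] = frac.fraction_pct
        report["cohorts"][cohort_name] = {
            "categories": vol.summarize_categories(calls),
            "contraction_fraction_pct": frac.fraction_pct,
            "n_timepoints": frac.n_timepoints,
            "truth_recovery": accuracy,
        }
    report["contraction_fractions_pct"] = fractions
    return report


def _run_afm(block: dict, seed: int, out: Path) -> dict:
    block = dict(block or {})
    shared = {k: v for k, v in block.items() if k != "regions"}
    regions = block.get("regions") or {
        "bulge": {"e_true_pa": 1196.0, "e_sd_pa": 534.0},
        "HG": {"e_true_pa": 747.3, "e_sd_pa": 414.3},
    }
    report: dict = {"regions": {}}
    values: dict[str, np.ndarray] = {}
    for idx, (region, cfg) in enumerate(regions.items()):  # declared order
        params = _params_with(
            synth.AfmSimParams, {**shared, **(cfg or {}), "region": region}, seed + idx
        )
        fmap = synth.gen_force_map(params)
        fio.write_force_map(fmap, out / f"afm_{region}.csv", map_id=region)
        summary = afm.map_stiffness(
            fmap,
            geometry=params.geometry,
            poisson=params.poisson,
            tip_parameter=params.tip_parameter,
        )
        values[region] = np.array([r.e_pa for r in summary.results if r.ok])
        report["regions"][region] = {
            "mean_pa": summary.mean_pa,
            "sd_pa": summary.sd_pa,
            "median_pa": summary.median_pa,
            "n_points": summary.n_ok,
            "n_failed": summary.n_failed,
        }
    names = list(values)
    if len(names) >= 2:
        a, b = names[0], names[1]
        comp = afm.compare_regions(values[a], values[b])
        report["comparison"] = {
            "regions": [a, b],
            "u_statistic": comp.u_statistic,
            "p_value": comp.p_value,
            "percent_stiffer": afm.percent_stiffer(comp.mean_a, comp.mean_b),
        }
    return report


def _run_mechano(block: dict, seed: int, out: Path) -> dict:
    block = dict(block or {})
    n_resamples = int(block.pop("n_resamples", 1000))
    params = _params_with(synth.MechSimParams, block, seed)
    records = synth.gen_cell_mech(params)
    fio.write_cell_records(records, out / "mechano_records.csv")
    test = mechano.permutation_inverse_correlation(
        records, n_resamples=n_resamples, seed=seed
    )
    evaluation = mechano.evaluate_state_classifier(records)
    return {
        "spearman_r": test.statistic,
        "p_value": test.p_value,
        "n_resamples": test.n_resamples,
        "classifier_accuracy": evaluation["accuracy"],
        "n_cells": evaluation["n"],
    }


def _run_expression(block: dict, seed: int, out: Path) -> dict:
    block = dict(block or {})
    n_bins = int(block.pop("n_bins", 25))
    n_ctrl = int(block.pop("n_ctrl", 50))
    if "actin_effect" in block and isinstance(block["actin_effect"], dict):
        block["actin_effect"] = tuple(block["actin_effect"].items())
    if "populations" in block and isinstance(block["populations"], dict):
        block["populations"] = tuple(block["populations"].items())
    params = _params_with(synth.ExprSimParams, block, seed)
    adata, gene_set = synth.gen_expression(params)
    fio.write_expression(adata, out / "expression")
    normed = actin.normalize_counts(adata)
    result = actin.module_score(normed, gene_set, n_bins=n_bins, n_ctrl=n_ctrl, seed=seed)
    summary = result.population_summary()
    return {
        "population_scores": {
            pop: {"mean": float(row["mean"]), "sd": float(row["sd"]), "n": int(row["n"])}
            for pop, row in summary.iterrows()
        },
        "top_population": str(summary["mean"].idxmax()),
    }


def _run_recoil(block: dict, seed: int, out: Path) -> dict:
    block = dict(block or {})
    n_per_group = int(block.pop("n_per_group", 12))
    groups = {
        "control": dict(block.pop("control", {}) or {}),
        "treated": {**synth.TREATED_RECOIL_PRESET, **(block.pop("treated", {}) or {})},
    }
    fits = {}
    for g_idx, (group, cfg) in enumerate(groups.items()):
        group_fits = []
        for j in range(n_per_group):
            params = _params_with(
                synth.RecoilSimParams, {**block, **cfg}, seed + 1000 * g_idx + j
            )
            trace = synth.gen_recoil(params)
            if j == 0:
                fio.write_recoil(trace, out / f"recoil_{group}.csv")
            group_fits.append(rc.fit_recoil(trace))
        fits[group] = group_fits
    comparison = rc.compare_recoil(fits["control"], fits["treated"])
    return comparison


def _run_targets(block: dict, seed: int, out: Path) -> dict:
    block = dict(block or {})
    planted = tuple(tuple(p) for p in block.pop("planted", []))
    params = _params_with(synth.UtrSimParams, {**block, "planted_sites": planted}, seed)
    utrs, truth, chance = synth.gen_utrs(params)
    fio.write_fasta([(u.gene, u.sequence) for u in utrs], out / "utrs.fasta")
    from . import targets as tg

    mirna = tg.MicroRNA("query", params.mirna_sequence)
    table = tg.count_sites_per_gene(mirna, utrs)
    total_by_type = {t: sum(row[t] for row in table.values()) for t in tg.SITE_TYPES}
    recovered = 0
    for entry in truth:
        hits = [
            s
            for u in utrs
            if u.gene == entry["gene"]
            for s in tg.find_seed_sites(mirna, u)
            if s.site_type == entry["site_type"]
            and abs(s.start - entry["position"]) <= 1
        ]
        recovered += bool(hits)
    return {
        "site_counts_by_type": total_by_type,
        "n_planted": len(truth),
        "n_planted_recovered": recovered,
        "n_chance_sites": len(chance),
    }


_RUNNERS = {
    "volume": _run_volume,
    "afm": _run_afm,
    "mechano": _run_mechano,
    "expression": _run_expression,
    "recoil": _run_recoil,
    "targets": _run_targets,
}


def run_scenario(scenario: dict | str, out_dir, seed: int | None = None) -> dict:
    """Run every block of a scenario; returns the report dict.

    ``scenario`` may be a path to a YAML file or an already-loaded mapping.
    ``seed`` overrides the scenario's global seed; one of the two must be set.
    """
    if not isinstance(scenario, dict):
        scenario = load_scenario(scenario)
    else:
        unknown = set(scenario) - _TOP_KEYS
        if unknown:
            raise ConfigError(
                f"unknown scenario keys {sorted(unknown)}; valid keys: {sorted(_TOP_KEYS)}"
            )
    if seed is None:
        seed = scenario.get("seed")
    if seed is None:
        raise ConfigError("no seed: set 'seed' in the scenario or pass one explicitly")
    seed = int(seed)

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _child_seeds(seed)
    report: dict = {"name": scenario.get("name", "scenario"), "seed": seed, "results": {}}
    for module in _MODULE_ORDER:
        if module in scenario and scenario[module] is not None:
            report["results"][module] = _RUNNERS[module](scenario[module], seeds[module], out)

    report_text = json.dumps(report, indent=2, sort_keys=True, default=float)
    (out / "report.json").write_text(report_text)
    manifest = {
        "name": report["name"],
        "version": __version__,
        "seed": seed,
        "module_seeds": seeds,
        "parameters": {k: scenario[k] for k in _MODULE_ORDER if k in scenario},
        "report_sha256": hashlib.sha256(report_text.encode()).hexdigest(),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return report
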