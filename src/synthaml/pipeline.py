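"""End-to-end study pipeline: simulate or load -> split -> fit -> sample ->
evaluate (fidelity, survival fidelity, privacy, comparisons, concordance)
-> report.

Every stochastic stage gets its own seed derived from one global seed, so a
run is reproducible from its serialized config alone.  Failure of one
evaluation stage is recorded and does not abort the others.
"""

from __future__ import annotations

import dataclasses
import json
import hashlib
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .compare import (alteration_frequencies, baseline_table,
                      concordance_matrix, cooccurrence_diff, outcome_table,
                      univariable_panel)
from .fidelity import fidelity_report
from .fixtures import default_config, simulate_cohort, split_train_test
from .generator import fit_generator, sample_synthetic, tune_generator
from .privacy import (bin_numeric_for_privacy, partition_training,
                      privacy_leakage_coefficient)
from .schema import CohortTable, bin_numeric, load_cohort, write_cohort
from .survfid import survival_fidelity_report

__all__ = ["RunConfig", "run_pipeline", "render_report", "derive_seeds"]


@dataclass
class RunConfig:
    seed: int = 0
    n: int = 1606
    original_csv: str | None = None      # load instead of simulating
    schema_path: str | None = None
    synthetic_csvs: dict = field(default_factory=dict)  # label -> path
    train_fraction: float = 0.8
    tune_budget: int = 0                 # 0 = default hyperparameters
    evaluate: tuple = ("fidelity", "survival_fidelity", "privacy",
                       "baseline", "outcome", "alterations",
                       "cooccurrence", "concordance")
    outdir: str | None = None

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def derive_seeds(global_seed: int) -> dict:
    """Fan the global seed out to stage seeds (all below 2**31)."""
    ss = np.random.SeedSequence(global_seed)
    names = ("simulate", "split", "fit", "sample", "partition", "tune")
    children = ss.spawn(len(names))
    return {nm: int(ch.generate_state(1)[0] % (2 ** 31))
            for nm, ch in zip(names, children)}


def run_pipeline(config: RunConfig) -> dict:
    """Execute the study end to end; returns (and optionally writes) the
    report bundle as plain dict / DataFrame entries."""
    seeds = derive_seeds(config.seed)
    bundle: dict = {"config": config.to_dict(), "seeds": seeds,
                    "version": __version__, "errors": {}}
    hashed = {k: v for k, v in config.to_dict().items() if k != "outdir"}
    bundle["config_hash"] = hashlib.sha256(
        json.dumps(hashed, sort_keys=True).encode()).hexdigest()[:16]

    # --- obtain the original cohort -------------------------------------
    if config.original_csv:
        original = load_cohort(config.original_csv, config.schema_path,
                               label="original")
        ground_truth = None
    else:
        fix_cfg = default_config(seed=seeds["simulate"], n=config.n)
        original, ground_truth = simulate_cohort(fix_cfg, label="original")
    bundle["n_original"] = original.n

    # --- split / fit / sample (skipped if synthetics are supplied) ------
    synthetics: dict[str, CohortTable] = {}
    if config.synthetic_csvs:
        for lab, path in config.synthetic_csvs.items():
            synthetics[lab] = load_cohort(path, config.schema_path, label=lab)
        train, test = split_train_test(original, config.train_fraction,
                                       seed=seeds["split"])
    else:
        train, test = split_train_test(original, config.train_fraction,
                                       seed=seeds["split"])
        hp = None
        if config.tune_budget > 0:
            tuning = tune_generator(train, test, budget=config.tune_budget,
                                    seed=seeds["tune"])
            hp = tuning.best_params
            bundle["tuning"] = {"best_params": tuning.best_params,
                                "best_objective": tuning.best_objective,
                                "trace": [tr["objective"] for tr in tuning.trace]}
        model = fit_generator(train, hp, seed=seeds["fit"])
        synthetics["copula"] = sample_synthetic(model, original.n,
                                                seed=seeds["sample"])
        bundle["model_meta"] = model.fit_meta
    bundle["synthetic_labels"] = list(synthetics)

    # --- evaluations, each isolated -------------------------------------
    def stage(name, fn):
        if name not in config.evaluate:
            return
        try:
            bundle[name] = fn()
        except Exception as exc:
            warnings.warn(f"stage {name} failed: {exc}")
            bundle["errors"][name] = str(exc)

    first = next(iter(synthetics.values()))
    stage("fidelity", lambda: {
        lab: fidelity_report(original, syn).to_dict()
        for lab, syn in synthetics.items()})
    stage("survival_fidelity", lambda: {
        lab: {ep: survival_fidelity_report(original, syn, ep).to_dict()
              for ep in ("os", "efs")}
        for lab, syn in synthetics.items()})

    def _privacy():
        out = {}
        for lab, syn in synthetics.items():
            subsets_raw = partition_training(train, test.n, k=4,
                                             seed=seeds["partition"])
            b_syn = bin_numeric_for_privacy(syn, original)
            b_test = bin_numeric_for_privacy(test, original)
            b_subs = [bin_numeric_for_privacy(s, original) for s in subsets_raw]
            rep = privacy_leakage_coefficient(
                b_syn, b_subs, b_test, syn_raw=syn, original_raw=original,
                partition_seed=seeds["partition"])
            out[lab] = rep.to_dict()
        return out

    stage("privacy", _privacy)
    stage("baseline", lambda: baseline_table(original, synthetics))
    stage("outcome", lambda: outcome_table(original, synthetics))
    stage("alterations", lambda: alteration_frequencies(original, synthetics))
    stage("cooccurrence", lambda: {
        lab: cooccurrence_diff(original, syn) for lab, syn in synthetics.items()})

    def _concordance():
        panel_real = univariable_panel(original)
        out = {}
        for lab, syn in synthetics.items():
            summary = concordance_matrix(panel_real, univariable_panel(syn))
            out[lab] = {"cells": summary.cells, "counts": summary.counts,
                        "inverse_count": summary.inverse_count}
        return out

    stage("concordance", _concordance)

    if ground_truth is not None:
        bundle["ground_truth_os_median"] = ground_truth.analytic_os_median

    if config.outdir:
        _write_bundle(bundle, original, synthetics, Path(config.outdir))
    return bundle


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and not np.isfinite(obj):
        return str(obj)
    return obj


def _write_bundle(bundle: dict, original, synthetics, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    json_doc = {}
    for key, val in bundle.items():
        if isinstance(val, pd.DataFrame):
            val.to_csv(outdir / f"{key}.csv", index=False)
        elif key == "cooccurrence":
            for lab, mat in val.items():
                mat.to_csv(outdir / f"cooccurrence_{lab}.csv")
        elif key == "concordance":
            doc = {}
            for lab, entry in val.items():
                entry["cells"].to_csv(outdir / f"concordance_{lab}.csv", index=False)
                doc[lab] = {"counts": entry["counts"],
                            "inverse_count": entry["inverse_count"]}
            json_doc[key] = doc
        else:
            json_doc[key] = _jsonable(val)
    with open(outdir / "bundle.json", "w") as fh:
        json.dump(json_doc, fh, indent=1, allow_nan=True)
    write_cohort(original, outdir / "original.csv", outdir / "schema.json")
    for lab, syn in synthetics.items():
        write_cohort(syn, outdir / f"synthetic_{lab}.csv")
    with open(outdir / "report.md", "w") as fh:
        fh.write(render_report(bundle))


def render_report(bundle: dict) -> str:
    """Human-readable markdown summary of a pipeline bundle."""
    lines = ["# Synthetic-cohort evaluation report", ""]
    lines.append(f"- config hash: `{bundle.get('config_hash', '')}`; "
                 f"seed fan-out: {bundle.get('seeds', {})}")
    lines.append(f"- original cohort: n={bundle.get('n_original')}; "
                 f"synthetic cohorts: {', '.join(bundle.get('synthetic_labels', [])) or 'none'}")
    lines.append("")

    priv = bundle.get("privacy", {})
    for lab, rep in priv.items():
        if rep.get("breach_flag"):
            lines += ["## WARNING: potential privacy breach",
                      f"Cohort **{lab}**: leakage coefficient "
                      f"{rep['leakage_coefficient']} exceeds threshold "
                      f"{rep['threshold']}. {rep.get('note', '')}", ""]

    if "fidelity" in bundle:
        lines.append("## Fidelity scores")
        for lab, rep in bundle["fidelity"].items():
            lines.append(f"- {lab}: RSC {rep['rsc']:.2f}, BSM {rep['bsm']:.2f}, "
                         f"LTCS {rep['ltcs']:.2f}")
        lines.append("")
    if "survival_fidelity" in bundle:
        lines.append("## Survival fidelity")
        for lab, eps in bundle["survival_fidelity"].items():
            for ep, rep in eps.items():
                lines.append(
                    f"- {lab} / {rep['endpoint']}: KM-divergence "
                    f"{rep['km_divergence_score']:.2f}, optimism "
                    f"{rep['optimism_score']:.2f} (signed "
                    f"{rep['signed_optimism']:+.3f}), short-sightedness "
                    f"{rep['short_sightedness_score']:.2f}")
        lines.append("")
    if priv:
        lines.append("## Privacy")
        for lab, rep in priv.items():
            lines.append(
                f"- {lab}: syn->train {rep['avg_min_dist_syn_train']:.4f}, "
                f"syn->test {rep['avg_min_dist_syn_test']:.4f}, leakage "
                f"coefficient {rep['leakage_coefficient']:.4f} "
                f"(threshold {rep['threshold']}), exact matches "
                f"{rep.get('exact_matches')}")
        lines.append("")
    if "concordance" in bundle:
        lines.append("## Univariable concordance")
        for lab, entry in bundle["concordance"].items():
            counts = entry["counts"] if isinstance(entry, dict) else entry
            lines.append(f"- {lab}: {counts.get('counts', counts)} "
                         f"(inverse effects: {entry.get('inverse_count', '?')})")
        lines.append("")
    for key in ("baseline", "outcome", "alterations"):
        if isinstance(bundle.get(key), pd.DataFrame):
            df = bundle[key]
            lines.append(f"## {key.capitalize()} table")
            lines.append(df.to_string(index=False, max_rows=40))
            lines.append("")
    if bundle.get("errors"):
        lines.append("## Stage errors")
        for k, v in bundle["errors"].items():
            lines.append(f"- {k}: {v}")
    return "\n".join(lines) + "\n"
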