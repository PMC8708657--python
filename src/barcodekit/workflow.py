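"""End-to-end orchestration of the comparative workflow.

curate -> (aligned path: distances -> identification criteria + gap
partitioning) and (alignment-free path: featurize -> classifier grid ->
final evaluation + ranking) -> unified report.

Outputs under the run directory: ``report.json`` (all summary numbers,
sorted keys), ``tables/*.tsv`` (per-record and per-cell tables), and
``run.log`` (per-stage wall-clock timings; the only file allowed to differ
between identical runs).
"""

from __future__ import annotations

import json
import time
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import abgd, classify, compare, features, identify, io, synth
from .distances import distance_matrix
from .errors import ConfigError, DataError

_DEF_SUPERVISED = {
    "schemes": ["spectrum", "gappy"],
    "k_values": [2, 3],
    "nn_values": [1, 3],
    "classifiers": ["knn", "rf"],
    "baseline": "knn",
    "folds": 10,
    "repeats": 2,
    "seed": 1,
    "gappy_g": 1,
    "mismatch_m": 1,
}

_DEF_UNSUPERVISED = {
    "model": "simple",
    "threshold": 0.03,
    "pmin": 0.001,
    "pmax": 0.1,
    "steps": 10,
    "gap_width": 1.5,
}


@dataclass
class RunConfig:
    dataset: dict
    curate: dict = field(default_factory=dict)
    unsupervised: dict = field(default_factory=dict)
    supervised: dict = field(default_factory=dict)
    output_dir: str = "out"

    @classmethod
    def from_toml(cls, path: str | Path) -> "RunConfig":
        try:
            with open(path, "rb") as fh:
                raw = tomllib.load(fh)
        except FileNotFoundError as exc:
            raise ConfigError(f"config file not found: {path}") from exc
        except tomllib.TOMLDecodeError as exc:
            raise ConfigError(f"invalid config: {exc}") from exc
        if "dataset" not in raw:
            raise ConfigError("config needs a [dataset] section")
        return cls(
            dataset=raw["dataset"],
            curate=raw.get("curate", {}),
            unsupervised=raw.get("unsupervised", {}),
            supervised=raw.get("supervised", {}),
            output_dir=raw.get("output", {}).get("dir", "out"),
        )


def _load_dataset(cfg: RunConfig) -> io.BarcodeDataset:
    source = cfg.dataset.get("source", "synthetic")
    if source == "synthetic":
        params = dict(cfg.dataset.get("synthetic", {}))
        ds, _ = synth.generate_dataset(synth.SynthConfig(**params))
        return ds
    if source == "fasta":
        spec = cfg.dataset.get("fasta", {})
        if "path" not in spec:
            raise ConfigError("[dataset.fasta] needs a 'path'")
        delimiter = spec.get("delimiter", "|")
        fields = tuple(spec.get("fields", ("species", "accession")))
        return io.read_fasta(
            spec["path"],
            marker=spec.get("marker", ""),
            label_spec=io.LabelSpec(delimiter=delimiter, fields=fields),
        )
    raise ConfigError(f"unknown dataset source {source!r}")


def _resolve_threshold(threshold, dm, ds) -> float:
    if isinstance(threshold, str):
        if threshold.startswith("percentile:"):
            q = float(threshold.split(":", 1)[1])
            vals = identify.intraspecific_distances(dm, ds)
            return identify.percentile_threshold(vals, q)
        return float(threshold)
    return float(threshold)


def run_unsupervised(ds: io.BarcodeDataset, params: dict, tables_dir: Path) -> dict:
    """Identification criteria + gap-partition scan; returns report section."""
    p = {**_DEF_UNSUPERVISED, **params}
    dm = distance_matrix(ds, model=p["model"])
    threshold = _resolve_threshold(p["threshold"], dm, ds)

    criteria_rows = []
    outcome_rows = []
    for criterion in identify.CRITERIA:
        report = identify.identify_all(dm, ds, criterion=criterion, threshold=threshold)
        criteria_rows.append(
            {
                "criterion": criterion,
                "pct_correct": report.pct_correct,
                "pct_incorrect": report.pct_incorrect,
                "pct_ambiguous": report.pct_ambiguous,
                "pct_nomatch": report.pct_nomatch,
                "species_correct_pct": report.species_correct_pct,
                "true_species_pct": report.true_species_pct,
            }
        )
        for o in report.outcomes:
            outcome_rows.append(
                {
                    "criterion": criterion,
                    "record_id": o.record_id,
                    "category": o.category,
                    "best_distance": o.best_distance,
                    "best_match_ids": ",".join(o.best_match_ids),
                }
            )
    pd.DataFrame(criteria_rows).to_csv(
        tables_dir / "identification_summary.tsv", sep="\t", index=False
    )
    pd.DataFrame(outcome_rows).to_csv(
        tables_dir / "identification_outcomes.tsv", sep="\t", index=False
    )

    partitions = abgd.scan_priors(
        dm, p_min=p["pmin"], p_max=p["pmax"], steps=p["steps"], X=p["gap_width"]
    )
    abgd.partition_table(partitions, ds).to_csv(
        tables_dir / "partition_scan.tsv", sep="\t", index=False
    )
    selected = abgd.select_initial_partition(partitions)
    categories, selected_summary = abgd.categorize_groups(selected, ds)
    membership = [
        {"group": c.group_index, "tag": c.tag, "record_id": rid}
        for c in categories
        for rid in sorted(c.record_ids)
    ]
    pd.DataFrame(membership).to_csv(
        tables_dir / "partition_membership.tsv", sep="\t", index=False
    )
    return {
        "threshold": threshold,
        "model": p["model"],
        "criteria": {row["criterion"]: row for row in criteria_rows},
        "selected_partition": selected_summary,
    }


def _grid_features(ds, scheme, k, p):
    if scheme == "spectrum":
        return features.spectrum_features(ds, k=k)
    if scheme == "gappy":
        return features.gappy_features(ds, k=k, g=p["gappy_g"])
    if scheme == "mismatch":
        return features.mismatch_features(ds, k=k, m=min(p["mismatch_m"], k - 1))
    raise ConfigError(f"unknown alignment-free scheme {scheme!r}")


def run_supervised(ds: io.BarcodeDataset, params: dict, tables_dir: Path) -> dict:
    """Three-stage supervised evaluation; returns report section.

    Stage 1 screens the configured classifier families on the aligned
    encoding and ranks them against the baseline with the corrected t-test.
    Stage 2 runs the nearest-neighbour grid over alignment-free schemes x k
    x NN; the best cell is chosen by max accuracy with ties to smaller k,
    then smaller NN, then scheme order.  Stage 3 evaluates every classifier
    on the selected alignment-free featurization.
    """
    p = {**_DEF_SUPERVISED, **params}
    folds, repeats, seed = p["folds"], p["repeats"], p["seed"]
    ratio = 1.0 / (folds - 1)

    # stage 1: classifier screening on the aligned encoding
    aligned_fm = features.encode_alignment(ds)
    stage1_runs: dict[str, list[float]] = {}
    stage1_results: dict[str, classify.CVResult] = {}
    for name in p["classifiers"]:
        spec = classify.ClassifierSpec(name, params={"nn": 1}, seed=seed)
        res = classify.evaluate_cv(aligned_fm, spec, n_folds=folds, repeats=repeats, seed=seed)
        stage1_runs[name] = res.per_run_accuracies
        stage1_results[name] = res
    ranking = compare.rank_classifiers(stage1_runs, baseline=p["baseline"], test_train_ratio=ratio)
    ranking.to_csv(tables_dir / "stage1_ranking.tsv", sep="\t")

    # stage 2: nearest-neighbour grid over alignment-free settings
    grid_rows = []
    best = None
    for si, scheme in enumerate(p["schemes"]):
        for k in p["k_values"]:
            fm = _grid_features(ds, scheme, k, p)
            for nn in p["nn_values"]:
                spec = classify.ClassifierSpec("knn", params={"nn": nn}, seed=seed)
                res = classify.evaluate_cv(fm, spec, n_folds=folds, repeats=repeats, seed=seed)
                grid_rows.append(
                    {
                        "scheme": scheme,
                        "k": k,
                        "nn": nn,
                        "accuracy_pct": res.accuracy_pct,
                        "rmse": res.rmse,
                        "species_any_correct_pct": res.species_any_correct_pct,
                        "species_all_correct_pct": res.species_all_correct_pct,
                        "tpr1_species_pct": res.tpr1_species_pct,
                    }
                )
                key = (-res.accuracy_pct, k, nn, si)
                if best is None or key < best[0]:
                    best = (key, scheme, k, nn)
    grid = pd.DataFrame(grid_rows)
    grid.to_csv(tables_dir / "stage2_grid.tsv", sep="\t", index=False)
    _, best_scheme, best_k, best_nn = best

    # stage 3: final evaluation of every classifier on the selected setting
    final_fm = _grid_features(ds, best_scheme, best_k, p)
    final_results = []
    names = []
    tpr_rows = []
    for name in p["classifiers"]:
        spec = classify.ClassifierSpec(name, params={"nn": best_nn}, seed=seed)
        res = classify.evaluate_cv(final_fm, spec, n_folds=folds, repeats=repeats, seed=seed)
        final_results.append(res)
        names.append(name)
        for species, row in res.per_class.iterrows():
            tpr_rows.append(
                {"classifier": name, "species": species, "tpr": row["tpr"], "fpr": row["fpr"]}
            )
    final_table = classify.evaluation_report(final_results, names)
    final_table.to_csv(tables_dir / "stage3_final.tsv", sep="\t")
    pd.DataFrame(tpr_rows).to_csv(tables_dir / "per_class_rates.tsv", sep="\t", index=False)

    return {
        "stage1_ranking": {
            name: {k: (None if pd.isna(v) else v) for k, v in row.items()}
            for name, row in ranking.iterrows()
        },
        "stage2_best": {"scheme": best_scheme, "k": best_k, "nn": best_nn},
        "stage3": {
            name: dict(row) for name, row in final_table.iterrows()
        },
        "folds": folds,
        "repeats": repeats,
        "seed": seed,
    }


def run(cfg: RunConfig, outdir: str | Path | None = None) -> dict:
    """Execute the full pipeline; write report.json, tables/, run.log."""
    outdir = Path(outdir if outdir is not None else cfg.output_dir)
    tables_dir = outdir / "tables"
    tables_dir.mkdir(parents=True, exist_ok=True)
    timings: list[tuple[str, float]] = []

    def _timed(stage, fn, *args):
        t0 = time.perf_counter()
        out = fn(*args)
        timings.append((stage, time.perf_counter() - t0))
        return out

    ds = _timed("load", _load_dataset, cfg)
    if len(ds) == 0:
        raise DataError("dataset is empty; nothing to analyze")
    min_len = cfg.curate.get("min_length", 0)
    if min_len:
        ds = io.filter_min_length(ds, min_len)
    min_consp = cfg.curate.get("min_conspecifics", 1)
    if min_consp > 1:
        ds = io.filter_min_conspecifics(ds, min_consp)
    if len(ds) == 0:
        raise DataError("curation removed every record")
    summary = io.dataset_summary(ds)

    report = {"dataset": summary}
    report["unsupervised"] = _timed(
        "unsupervised", run_unsupervised, ds, cfg.unsupervised, tables_dir
    )
    report["supervised"] = _timed(
        "supervised", run_supervised, ds, cfg.supervised, tables_dir
    )

    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=float)
        fh.write("\n")
    with open(outdir / "run.log", "w") as fh:
        for stage, seconds in timings:
            fh.write(f"{stage}\t{seconds:.3f}s\n")
    return report
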