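"""One-command orchestration of the full study design.

``run_pipeline`` executes: read (or generate) the library, compute both
descriptor sets, divide by both schemes, binarize activities per cell
line, fit and evaluate all four back-ends, assemble the results grids with
sigma columns, compare the division schemes with a paired t-test, and
build the SAR suggestion report.  All randomness derives from the config
seed; a manifest records every parameter so a run can be replayed.
"""

from __future__ import annotations

import json
import platform
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from importlib.metadata import version as _dist_version

from cycloqsar.chem_io import (
    CELL_LINES,
    CYCLOPAMINE_IC50,
    CompoundLibrary,
    join_library,
    read_activity_table,
    read_structures,
)
from cycloqsar.descriptors import build_matrix, normalize
from cycloqsar.division import cluster_diverse_split, default_k, rank_diverse, split_by_rank
from cycloqsar.evaluation import (
    PairedTTestResult,
    ResultsGrid,
    paired_ttest,
    render_grid,
    sigma_columns,
)
from cycloqsar.models import (
    PLSConfig,
    SVMConfig,
    SVRConfig,
    binarize,
    evaluate_classification,
    evaluate_regression,
    fit_binary_bayes,
    fit_pls,
    fit_svm,
    fit_svr,
)
from cycloqsar.sar import build_sar_report, match_scaffolds
from cycloqsar.synth import DEFAULT_SCAFFOLDS, GeneratorConfig, generate_library

ALL_MODELS = ("PLS", "SVR", "Bayes", "SVM")
ALL_DIVISIONS = ("diverse", "cluster_diverse")
ALL_DESCRIPTOR_SETS = ("general", "drug_like")
_SET_TAG = {"general": "general", "drug_like": "drug_like_index"}


@dataclass
class RunConfig:
    structures: Optional[str] = None  # None -> synthetic library
    activities: Optional[str] = None
    structure_format: str = "smiles"
    descriptor_sets: tuple[str, ...] = ALL_DESCRIPTOR_SETS
    divisions: tuple[str, ...] = ALL_DIVISIONS
    models: tuple[str, ...] = ALL_MODELS
    cell_lines: tuple[str, ...] = CELL_LINES
    cutoffs: dict[str, float] = field(default_factory=lambda: dict(CYCLOPAMINE_IC50))
    train_fraction: float = 0.65
    n_clusters: Optional[int] = None  # None -> about one cluster per 20
    bayes_bins: int = 25
    bayes_sigma: float = 0.25
    sar_cell_line: str = "NCI-H446"
    sar_descriptor_set: str = "general"
    sar_top_n: int = 10
    seed: int = 0
    out_dir: str = "results/run"

    def __post_init__(self) -> None:
        if not self.models or not self.cell_lines or not self.descriptor_sets:
            raise ValueError("need at least one model, cell line and descriptor set")
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train fraction must be in (0, 1)")
        for m in self.models:
            if m not in ALL_MODELS:
                raise ValueError(f"unknown model {m!r}")
        for d in self.divisions:
            if d not in ALL_DIVISIONS:
                raise ValueError(f"unknown division {d!r}")
        for s in self.descriptor_sets:
            if s not in ALL_DESCRIPTOR_SETS:
                raise ValueError(f"unknown descriptor set {s!r}")


def validate_config(raw: str | dict) -> RunConfig:
    """Parse a JSON config (text or dict); unknown keys are rejected."""
    if isinstance(raw, str):
        raw = raw.strip()
        data = json.loads(raw) if raw else {}
    else:
        data = dict(raw)
    known = set(RunConfig.__dataclass_fields__)
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    for key in ("descriptor_sets", "divisions", "models", "cell_lines"):
        if key in data:
            data[key] = tuple(data[key])
    return RunConfig(**data)


def _load_library(config: RunConfig) -> CompoundLibrary:
    if config.structures is None:
        library, _ = generate_library(GeneratorConfig(seed=config.seed))
        return library
    mols, failures = read_structures(config.structures, config.structure_format)
    acts = read_activity_table(config.activities)
    lib = join_library(mols, acts, cell_lines=config.cell_lines, strict=False)
    lib.warnings.extend(f"parse failure: {f.reason} (record {f.index})" for f in failures)
    return lib


@dataclass
class RunResult:
    grids: dict[str, ResultsGrid]
    sigma: dict[str, pd.DataFrame]
    ttest: Optional[PairedTTestResult]
    suggestions: Optional[pd.DataFrame]
    manifest: dict
    out_dir: Path


def run_pipeline(config: RunConfig) -> RunResult:
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log: list[str] = []

    def stage(name):
        def wrap(fn, *args, **kw):
            try:
                return fn(*args, **kw)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        return wrap

    library = stage("read")(_load_library, config)
    log.append(f"read: {len(library)} compounds")

    # descriptors + normalization per set (full library, before division)
    matrices = {}
    for ds in config.descriptor_sets:
        mat = stage("descriptors")(build_matrix, library, _SET_TAG[ds])
        norm_mat, _ = stage("descriptors")(normalize, mat)
        matrices[ds] = (mat, norm_mat)
        log.append(f"descriptors[{ds}]: {norm_mat.values.shape[1]} columns retained")

    y_log = {
        cl: np.array(
            [np.log10(r.ic50(cl)) if r.ic50(cl) is not None else np.nan for r in library]
        )
        for cl in config.cell_lines
    }
    labelings = {
        cl: binarize(library, cl, config.cutoffs[cl]) for cl in config.cell_lines
    }

    grids: dict[str, ResultsGrid] = {}
    sigma_tables: dict[str, pd.DataFrame] = {}
    for division in config.divisions:
        records = []
        for ds in config.descriptor_sets:
            raw, norm_mat = matrices[ds]
            n = len(norm_mat.compound_ids)
            if division == "diverse":
                ranking = rank_diverse(norm_mat, start=0)
                split = split_by_rank(ranking, config.train_fraction)
            else:
                k = config.n_clusters or default_k(n)
                split, _ = cluster_diverse_split(
                    norm_mat, k=k, frac=config.train_fraction, seed=config.seed
                )
            tr, te = split.train_indices, split.test_indices
            log.append(f"division[{division}/{ds}]: train {len(tr)} / test {len(te)}")
            X = raw.values  # models handle their own scaling
            id_index = {cid: i for i, cid in enumerate(raw.compound_ids)}
            for cl in config.cell_lines:
                yv = y_log[cl]
                ok = ~np.isnan(yv[: len(raw.compound_ids)])
                tr_r = np.array([i for i in tr if ok[i]])
                te_r = np.array([i for i in te if ok[i]])
                if "PLS" in config.models:
                    rep = evaluate_regression(
                        lambda A, b: fit_pls(A, b, PLSConfig()),
                        X[tr_r], yv[tr_r], X[te_r], yv[te_r],
                    )
                    records += _reg_records("PLS", cl, ds, rep)
                if "SVR" in config.models:
                    rep = evaluate_regression(
                        lambda A, b: fit_svr(A, b, SVRConfig()),
                        X[tr_r], yv[tr_r], X[te_r], yv[te_r],
                    )
                    records += _reg_records("SVR", cl, ds, rep)
                lab = labelings[cl]
                lab_idx = {cid: v for cid, v in zip(lab.ids, lab.labels)}
                tr_c = np.array([i for i in tr if raw.compound_ids[i] in lab_idx])
                te_c = np.array([i for i in te if raw.compound_ids[i] in lab_idx])
                ytr = np.array([lab_idx[raw.compound_ids[i]] for i in tr_c])
                yte = np.array([lab_idx[raw.compound_ids[i]] for i in te_c])
                if "Bayes" in config.models:
                    rep = evaluate_classification(
                        lambda A, b: fit_binary_bayes(
                            A, b, config.bayes_bins, config.bayes_sigma
                        ),
                        X[tr_c], ytr, X[te_c], yte,
                    )
                    records += _cls_records("Bayes", cl, ds, rep)
                if "SVM" in config.models:
                    rep = evaluate_classification(
                        lambda A, b: fit_svm(A, b, SVMConfig()),
                        X[tr_c], ytr, X[te_c], yte,
                    )
                    records += _cls_records("SVM", cl, ds, rep)
        grid = ResultsGrid.from_records(records, division)
        grids[division] = grid
        sig = sigma_columns(grid)
        sigma_tables[division] = sig.table
        render_grid(grid, sig).to_csv(out_dir / f"grid_{division}.csv", index=False)
        sig.table.to_csv(out_dir / f"sigma_{division}.csv", index=False)

    ttest = None
    if len(grids) == 2:
        a, b = (grids[d] for d in config.divisions)
        ttest = paired_ttest(a, b)
        with open(out_dir / "ttest.json", "w") as fh:
            json.dump(
                {
                    "t": ttest.t, "p": ttest.p, "n_pairs": ttest.n,
                    "degenerate": ttest.degenerate,
                    "pairing": "all (model, metric, cell line, descriptor set) cells, sigma excluded",
                },
                fh, indent=2,
            )

    suggestions = None
    if config.sar_cell_line in config.cell_lines:
        ds = config.sar_descriptor_set
        raw, _ = matrices.get(ds, matrices[config.descriptor_sets[0]])
        lab = labelings[config.sar_cell_line]
        id_index = {cid: i for i, cid in enumerate(raw.compound_ids)}
        rows = [id_index[c] for c in lab.ids if c in id_index]
        Xl = raw.values[rows]
        yl = np.array([lab.labels[i] for i, c in enumerate(lab.ids) if c in id_index])
        model = fit_binary_bayes(Xl, yl, config.bayes_bins, config.bayes_sigma)
        report = build_sar_report(
            model, library, DEFAULT_SCAFFOLDS,
            descriptor_set=_SET_TAG[ds], top_n=config.sar_top_n,
            descriptor_names=raw.names,
        )
        suggestions = report.table
        suggestions.to_csv(out_dir / "suggestions.csv", index=False)

    manifest = {
        "package_version": _dist_version("cycloqsar"),
        "python": platform.python_version(),
        "config": _jsonable(asdict(config)),
        "log": log,
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return RunResult(grids, sigma_tables, ttest, suggestions, manifest, out_dir)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def _reg_records(model, cell_line, ds, rep):
    return [
        {"model": model, "metric": m, "cell_line": cell_line,
         "descriptor_set": ds, "value": v}
        for m, v in (("R2", rep.R2), ("Q2", rep.Q2), ("r2", rep.r2))
    ]


def _cls_records(model, cell_line, ds, rep):
    return [
        {"model": model, "metric": m, "cell_line": cell_line,
         "descriptor_set": ds, "value": v}
        for m, v in (("At", rep.At.value), ("Av", rep.Av.value), ("Ap", rep.Ap.value))
    ]
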