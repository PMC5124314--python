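"""High-level encode / train-eval / scan workflows.

These functions tie the modules into the end-to-end pipelines the CLI and
the example scripts expose: load (or simulate) precursors, build labeled
windows, encode, cross-validate or fit a final model, and scan precursors
for cleavage sites.  All randomness (fold shuffling, simulation) flows
from the single seed in the configuration.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as _io
from .dataset import make_examples
from .encoding import EncodingScheme, encode_windows
from .model import (
    METRIC_NAMES,
    cross_validate,
    eae_profile,
    end_absolute_error,
    fit,
    save_model,
    scan_precursor,
)
from .structure import annotate_loops, max_loop_length, parse_dotbracket

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "build_windows",
    "dataset_max_loop_length",
    "encode_dataset",
    "train_eval",
    "grid_train_eval",
    "scan_dataset",
]

GRID_WINDOW_SIZES = (8, 10, 12, 14)
GRID_KS = (1, 2, 3, 4, 5)


@dataclass(frozen=True)
class RunConfig:
    """Resolved run settings shared by the workflows."""

    scheme: str = "lbsize"
    w: int = 14
    k: int = 1
    offset: int = 6
    direction: str = "toward-apex"
    gamma: float | None = None
    cost: float = 1.0
    folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.w < 2 or self.w % 2 != 0:
            raise ValueError(f"window size must be even and >= 2, got {self.w}")
        if self.k < 1:
            raise ValueError(f"k must be >= 1, got {self.k}")
        if self.folds < 2:
            raise ValueError(f"folds must be >= 2, got {self.folds}")
        if self.offset < 1:
            raise ValueError(f"offset must be >= 1, got {self.offset}")

    def asdict(self) -> dict:
        return dataclasses.asdict(self)


def dataset_max_loop_length(precursors) -> int:
    """Global M: maximum loop/bulge run length over all precursors."""
    return max_loop_length(
        annotate_loops(parse_dotbracket(p.structure)) for p in precursors
    )


def build_windows(precursors, config: RunConfig):
    """Labeled windows for all precursors plus the dataset scheme.

    M is measured on these precursors and frozen into the returned
    :class:`EncodingScheme`; encoding any later data must reuse it.
    """
    windows = []
    for p in precursors:
        windows.extend(
            make_examples(
                p, config.w, offset=config.offset, direction=config.direction
            )
        )
    M = dataset_max_loop_length(precursors)
    scheme = EncodingScheme(name=config.scheme, w=config.w, k=config.k, M=M)
    return windows, scheme


def encode_dataset(precursors, config: RunConfig, outdir) -> dict[str, str]:
    """Windows TSV plus one sparse feature file per arm; returns paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    windows, scheme = build_windows(precursors, config)
    logger.info(
        "encoded %d windows under %s (w=%d, k=%d, M=%d)",
        len(windows),
        scheme.name,
        scheme.w,
        scheme.k,
        scheme.M,
    )
    paths = {"windows": str(outdir / "windows.tsv")}
    _io.write_windows(windows, paths["windows"])
    for arm in ("5p", "3p"):
        arm_windows = [w for w in windows if w.arm == arm]
        if not arm_windows:
            continue
        X, y = encode_windows(arm_windows, scheme)
        path = outdir / f"features_{arm}.svmlight"
        _io.write_features(X, y, path)
        paths[f"features_{arm}"] = str(path)
    scheme_path = outdir / "scheme.tsv"
    pd.DataFrame([dataclasses.asdict(scheme)]).to_csv(
        scheme_path, sep="\t", index=False
    )
    paths["scheme"] = str(scheme_path)
    return paths


def _report_rows(scheme: EncodingScheme, results) -> list[dict]:
    rows = []
    for arm, res in results.items():
        for f, pf in enumerate(res.per_fold):
            rows.append(
                {
                    "method": scheme.name,
                    "w": scheme.w,
                    "k": scheme.k,
                    "arm": arm,
                    "fold": f,
                    **{m: pf[m] for m in METRIC_NAMES},
                }
            )
        for stat, values in (("mean", res.mean), ("variance", res.variance)):
            rows.append(
                {
                    "method": scheme.name,
                    "w": scheme.w,
                    "k": scheme.k,
                    "arm": arm,
                    "fold": stat,
                    **{m: values[m] for m in METRIC_NAMES},
                }
            )
    return rows


def train_eval(precursors, config: RunConfig, outdir=None, fit_final=True):
    """Cross-validated evaluation plus final per-arm models on all windows.

    Returns ``(results, models)``: both map arm -> EvalResult /
    TrainedModel (``models`` is None with ``fit_final=False``).  Training
    is per arm throughout, mirroring the evaluation protocol (the two
    arms are separate classification problems; pooling them would let a
    5p window shifted toward the terminus mimic the 3p positive pattern).
    When ``outdir`` is given, writes the per-fold report, pooled ROC
    points, and the model archive.
    """
    windows, scheme = build_windows(precursors, config)
    results = cross_validate(
        windows,
        scheme,
        folds=config.folds,
        gamma=config.gamma,
        cost=config.cost,
        seed=config.seed,
    )
    models = None
    if fit_final:
        models = {}
        for arm in results:
            X, y = encode_windows([w for w in windows if w.arm == arm], scheme)
            models[arm] = fit(X, y, scheme, gamma=config.gamma, cost=config.cost)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        report = pd.DataFrame(_report_rows(scheme, results))
        report.attrs["config"] = config.asdict()
        report.to_csv(outdir / "report.tsv", sep="\t", index=False)
        for arm, res in results.items():
            fpr, tpr = res.roc
            pd.DataFrame({"FPR": fpr, "TPR": tpr}).to_csv(
                outdir / f"roc_{arm}.tsv", sep="\t", index=False
            )
        if models is not None:
            save_model(models, outdir / "model.joblib")
    return results, models


def grid_train_eval(precursors, config: RunConfig, outdir=None) -> pd.DataFrame:
    """Sweep w in {8,10,12,14} x k in {1..5} and tabulate mean CV metrics.

    For non-lbsize schemes k is irrelevant and only k=1 is evaluated.
    """
    rows = []
    ks = GRID_KS if config.scheme == "lbsize" else (1,)
    for w in GRID_WINDOW_SIZES:
        for k in ks:
            cfg = dataclasses.replace(config, w=w, k=k)
            windows, scheme = build_windows(precursors, cfg)
            results = cross_validate(
                windows,
                scheme,
                folds=cfg.folds,
                gamma=cfg.gamma,
                cost=cfg.cost,
                seed=cfg.seed,
            )
            for arm, res in results.items():
                rows.append(
                    {
                        "method": scheme.name,
                        "w": w,
                        "k": k,
                        "arm": arm,
                        **{m: res.mean[m] for m in METRIC_NAMES},
                    }
                )
    table = pd.DataFrame(rows)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        table.to_csv(outdir / "grid_summary.tsv", sep="\t", index=False)
    return table


def scan_dataset(model, precursors, truth=None, outdir=None):
    """Scan precursors for cleavage sites; EAE summary when truth is known.

    ``model`` is a TrainedModel or a per-arm dict (see
    :func:`lbsizecleav.model.scan_precursor`).
    ``truth`` maps precursor id -> (cd5p, cd3p).  Returns
    ``(predictions DataFrame, eae profile array or None)``.  Precursors
    too short for the model's window are reported and skipped.
    """
    rows = []
    profiles = {}
    for p in precursors:
        try:
            res = scan_precursor(model, p)
        except ValueError as exc:
            logger.warning("skipping %s: %s", p.id, exc)
            continue
        profiles[p.id] = res
        row = {
            "id": p.id,
            "predicted_cd5p": res.predicted_cd5p,
            "predicted_cd3p": res.predicted_cd3p,
        }
        if truth is not None and p.id in truth:
            cd5p, cd3p = truth[p.id]
            row["true_cd5p"], row["true_cd3p"] = cd5p, cd3p
            if res.predicted_cd5p is not None:
                row["eae_5p"] = end_absolute_error(res.predicted_cd5p, cd5p)
            if res.predicted_cd3p is not None:
                row["eae_3p"] = end_absolute_error(res.predicted_cd3p, cd3p)
        rows.append(row)
    predictions = pd.DataFrame(rows)
    profile = None
    if truth is not None and "eae_5p" in predictions.columns:
        errors = pd.concat(
            [predictions.get("eae_5p"), predictions.get("eae_3p")]
        ).dropna()
        profile = eae_profile(errors.astype(int))
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        predictions.to_csv(outdir / "predictions.tsv", sep="\t", index=False)
        for pid, res in profiles.items():
            pd.DataFrame({"site": res.sites, "score": res.scores}).to_csv(
                outdir / f"profile_{pid}.tsv", sep="\t", index=False
            )
        if profile is not None:
            pd.DataFrame(
                {"t": np.arange(len(profile)), "fraction_eae_le_t": profile}
            ).to_csv(outdir / "eae_profile.tsv", sep="\t", index=False)
    return predictions, profile
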