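"""End-to-end orchestration: generate -> mechanics -> features -> stats -> RF.

Each stage reads its predecessor's on-disk artifact (contour JSONs, the
feature CSV), so any stage can be rerun in isolation.  A run manifest
records the configuration snapshot, the seed, per-stage artifact hashes and
timings; re-running with the same manifest inputs reproduces the feature
table bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import pathlib
import time
from importlib.metadata import PackageNotFoundError, version

import pandas as pd

from .cohort import CohortConfig, generate_cohort, load_cohort, save_cohort
from .features import cohort_feature_table
from .forest import ProgressionForestClassifier
from .lme import correlation_screen

__all__ = ["run_all", "train_model", "PipelineError"]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage, artifacts are preserved."""


def _pkg_version() -> str:
    try:
        return version("plaquefatigue")
    except PackageNotFoundError:
        return "unknown"


def _sha256(path: pathlib.Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _hash_tree(path: pathlib.Path) -> str:
    h = hashlib.sha256()
    if path.is_dir():
        for f in sorted(path.rglob("*")):
            if f.is_file():
                h.update(f.name.encode())
                h.update(f.read_bytes())
    else:
        h.update(path.read_bytes())
    return h.hexdigest()


def train_model(table: pd.DataFrame, rf_kwargs: dict | None = None) -> dict:
    """Fit the self-tuning forest on a feature table and report it as JSON-able."""
    from .features import FACTOR_COLUMNS

    kwargs = dict(select=True, positive_label=0)
    kwargs.update(rf_kwargs or {})
    clf = ProgressionForestClassifier(**kwargs)
    clf.fit(table[FACTOR_COLUMNS], table["label"].to_numpy())
    res = clf.result()
    return {
        "mtry": res.mtry,
        "ntree": res.ntree,
        "ntree_stabilized": res.ntree_stabilized,
        "oob_error_pct": res.oob_error,
        "mtry_trace": res.mtry_trace,
        "ntree_trace": res.ntree_trace,
        "gini_importance": res.gini_importance.to_dict(),
        "selected_factors": res.selected_factors,
        "confusion": dataclasses.asdict(res.confusion),
        "metrics_pct": res.metrics,
        "positive_label": kwargs["positive_label"],
    }


def run_all(
    out_dir: str | pathlib.Path,
    cohort_config: CohortConfig | None = None,
    seed: int | None = None,
    surrogate: bool = True,
    feature_kwargs: dict | None = None,
    rf_kwargs: dict | None = None,
) -> dict:
    """Run the whole analysis and return the manifest (also written to disk).

    With ``surrogate=True`` the Laplace closed form replaces the FE solve in
    feature extraction — orders of magnitude faster, same table contract.
    """
    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = cohort_config or CohortConfig()
    if seed is not None:
        cfg = dataclasses.replace(cfg, seed=seed)

    manifest: dict = {
        "package_version": _pkg_version(),
        "seed": cfg.seed,
        "surrogate": surrogate,
        "config": dataclasses.asdict(cfg),
        "stages": {},
    }

    def stage(name, fn):
        t0 = time.perf_counter()
        try:
            artifact = fn()
        except Exception as exc:
            manifest["stages"][name] = {"status": "failed", "error": str(exc)}
            (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        entry = {
            "status": "ok",
            "seconds": round(time.perf_counter() - t0, 3),
            "artifact": str(artifact),
            "sha256": _hash_tree(pathlib.Path(artifact)),
        }
        manifest["stages"][name] = entry
        return artifact

    def _generate():
        cohort = generate_cohort(cfg)
        save_cohort(cohort, out / "contours")
        return out / "contours"

    contours_dir = stage("generate", _generate)

    def _features():
        pairs = load_cohort(contours_dir)
        mode = "surrogate" if surrogate else "fe"
        table = cohort_feature_table(pairs, mode=mode, **(feature_kwargs or {}))
        path = out / "features.csv"
        path.write_text(table.to_csv(index=False))
        return path

    features_path = stage("features", _features)

    def _correlate():
        table = pd.read_csv(features_path)
        screen = correlation_screen(table)
        path = out / "correlations.csv"
        path.write_text(screen.to_csv(index=False))
        return path

    stage("correlate", _correlate)

    def _train():
        table = pd.read_csv(features_path)
        kwargs = dict(rf_kwargs or {})
        kwargs.setdefault("seed", cfg.seed)
        report = train_model(table, kwargs)
        path = out / "model_report.json"
        path.write_text(json.dumps(report, indent=2))
        return path

    stage("train", _train)

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
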