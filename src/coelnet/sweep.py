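"""The feature-combination sweep and its summaries.

The central experiment: for each co-elution dataset and each sampled
combination of 0-9 external genomic features, train the co-complex
classifier, assemble a network, and evaluate the full outcome battery.
Trends of each outcome against the number of integrated features are then
summarized by Spearman correlations, and single-feature effects are
compared with the feature-free baseline.
"""

from __future__ import annotations

import itertools
import math
import traceback
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from coelnet.classifier import CoComplexModel, ComplexSet, derive_seed
from coelnet.evaluation import (
    AnnotationTable,
    evaluate_network,
)
from coelnet.genomic import FEATURE_KINDS, InteractionCatalog, attach_external_features
from coelnet.stats import bonferroni, brunner_munzel, fishers_method, spearman_trend

__all__ = [
    "CombinationPlan",
    "SweepConfig",
    "SweepResult",
    "enumerate_combinations",
    "run_sweep",
    "summarize",
    "METRICS",
]

METRICS = (
    "median_auroc",
    "novelty_fraction",
    "validation_rate",
    "bias_rho",
    "clustering_coefficient",
)


@dataclass
class CombinationPlan:
    """Sampled feature combinations, grouped by combination size."""

    combinations: list[tuple[str, ...]]
    seed: int = 0

    def __len__(self) -> int:
        return len(self.combinations)

    def by_size(self) -> dict[int, list[tuple[str, ...]]]:
        out: dict[int, list[tuple[str, ...]]] = {}
        for combo in self.combinations:
            out.setdefault(len(combo), []).append(combo)
        return out


def enumerate_combinations(
    features: Sequence[str] = FEATURE_KINDS,
    max_per_size: int = 10,
    seed: int = 0,
) -> CombinationPlan:
    """Plan the sweep's feature combinations.

    For each combination size m from 0 to len(features), all C(n, m)
    combinations are used when there are at most ``max_per_size`` of
    them; otherwise ``max_per_size`` distinct combinations are sampled
    without replacement (seeded).  Size 0 is the single empty combination
    (the dataset-features-only baseline).
    """
    features = list(features)
    if len(set(features)) != len(features):
        raise ValueError("feature names must be unique")
    rng = np.random.default_rng(seed & 0x7FFFFFFF)
    plan: list[tuple[str, ...]] = []
    for m in range(len(features) + 1):
        all_m = list(itertools.combinations(features, m))
        if len(all_m) <= max_per_size:
            plan.extend(all_m)
        else:
            picks = rng.choice(len(all_m), size=max_per_size, replace=False)
            plan.extend(all_m[i] for i in sorted(picks))
    return CombinationPlan(plan, seed=seed)


@dataclass
class SweepConfig:
    """Classifier and assembly settings shared across the sweep."""

    k_folds: int = 10
    top_n: int = 10000
    cutoff_year: int | None = None
    exclude_pmids: tuple[str, ...] = ()
    labeled_mode: str = "out_of_fold"
    eval_folds: int = 3
    seed: int = 0


@dataclass
class SweepResult:
    """Rows of (dataset, combination, metrics) plus recorded failures."""

    rows: list[dict] = field(default_factory=list)
    failures: list[dict] = field(default_factory=list)

    @property
    def df(self) -> pd.DataFrame:
        cols = ["dataset", "combination", "n_features", *METRICS, "n_edges", "n_terms"]
        return pd.DataFrame(self.rows, columns=cols)

    def baseline(self) -> pd.DataFrame:
        df = self.df
        return df[df["n_features"] == 0]


def _combo_label(combo: tuple[str, ...]) -> str:
    return "+".join(combo) if combo else "baseline"


def run_sweep(
    datasets: Mapping[str, pd.DataFrame],
    external: Mapping[str, pd.DataFrame],
    complexes: ComplexSet,
    plan: CombinationPlan,
    annotations: AnnotationTable,
    catalog: InteractionCatalog,
    publication_counts: pd.Series,
    config: SweepConfig,
    cache_dir=None,
) -> SweepResult:
    """Run the full (dataset x combination) sweep.

    ``datasets`` maps dataset ids to base pair-feature tables (the six
    dataset-derived features); ``external`` maps feature kinds to pair
    score tables.  Per cell the combination is attached, the classifier
    cross-validated with a seed derived from the master seed and the cell
    key, a top-N network assembled, and all outcomes evaluated.  Failures
    are recorded and the sweep continues.

    With ``cache_dir``, each completed row is written to a JSON file
    keyed by (dataset, combination, seed) and reloaded on rerun, so an
    interrupted sweep resumes where it stopped.
    """
    import json

    if cache_dir is not None:
        cache_dir = Path(cache_dir)
        cache_dir.mkdir(parents=True, exist_ok=True)
    result = SweepResult()
    for dataset_id, base_table in datasets.items():
        for combo in plan.combinations:
            cache_path = None
            if cache_dir is not None:
                key = derive_seed(config.seed, dataset_id, combo)
                cache_path = cache_dir / f"row_{dataset_id}_{key:08x}.json"
                if cache_path.exists():
                    with open(cache_path) as fh:
                        result.rows.append(json.load(fh))
                    continue
            try:
                table = attach_external_features(base_table, combo, external)
                cell_seed = derive_seed(config.seed, dataset_id, combo)
                model = CoComplexModel(table, complexes)
                res = model.fit(
                    k=config.k_folds, seed=cell_seed, labeled_mode=config.labeled_mode
                )
                network = res.top_n(config.top_n)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    report = evaluate_network(
                        network,
                        annotations,
                        catalog,
                        publication_counts,
                        cutoff_year=config.cutoff_year,
                        exclude_pmids=config.exclude_pmids,
                        n_folds=config.eval_folds,
                        seed=cell_seed,
                    )
                row = {
                    "dataset": dataset_id,
                    "combination": _combo_label(combo),
                    "n_features": len(combo),
                    "median_auroc": report.median_auroc,
                    "novelty_fraction": report.novelty_fraction,
                    "validation_rate": report.validation_rate,
                    "bias_rho": report.bias_rho,
                    "clustering_coefficient": report.clustering_coefficient,
                    "n_edges": report.n_edges,
                    "n_terms": report.n_terms,
                }
                result.rows.append(row)
                if cache_path is not None:
                    with open(cache_path, "w") as fh:
                        json.dump(row, fh)
            except Exception as exc:  # per-cell fault isolation
                result.failures.append(
                    {
                        "dataset": dataset_id,
                        "combination": _combo_label(combo),
                        "error": f"{type(exc).__name__}: {exc}",
                        "traceback": traceback.format_exc(),
                    }
                )
    return result


def single_feature_effects(result: SweepResult) -> pd.DataFrame:
    """Compare each single-feature condition with the m=0 baseline.

    For every feature and metric, the metric values of that feature's
    single-feature networks (across datasets) are compared with the
    baseline networks' values by a two-sided Brunner-Munzel test;
    P-values are Bonferroni-adjusted within each metric.
    """
    df = result.df
    base = df[df["n_features"] == 0]
    rows = []
    for metric in METRICS:
        metric_rows = []
        for feature in FEATURE_KINDS:
            sub = df[df["combination"] == feature]
            a = sub[metric].dropna().to_numpy()
            b = base[metric].dropna().to_numpy()
            delta = (
                float(np.median(a) - np.median(b)) if len(a) and len(b) else float("nan")
            )
            try:
                _, p = brunner_munzel(a, b)
            except ValueError:
                p = float("nan")
            metric_rows.append(
                {"feature": feature, "metric": metric, "median_delta": delta, "p": p}
            )
        ps = np.array([r["p"] for r in metric_rows])
        ok = ~np.isnan(ps)
        adjusted = np.full(len(ps), np.nan)
        if ok.any():
            adjusted[ok] = bonferroni(ps[ok])
        for r, p_adj in zip(metric_rows, adjusted):
            r["p_bonferroni"] = float(p_adj) if not np.isnan(p_adj) else float("nan")
        rows.extend(metric_rows)
    return pd.DataFrame(rows)


def trend_table(result: SweepResult) -> pd.DataFrame:
    """Spearman trend of each metric against the number of features."""
    rows = []
    for metric in METRICS:
        try:
            rho, p = spearman_trend(result.df, metric)
        except ValueError:
            rho, p = float("nan"), float("nan")
        rows.append(
            {
                "metric": metric,
                "rho": rho,
                "p": p,
                "n": int(result.df[metric].notna().sum()),
            }
        )
    return pd.DataFrame(rows)


def summarize(result: SweepResult, outdir) -> dict[str, Path]:
    """Write machine-readable sweep summaries.

    Produces per-metric scatter tables (one point per network), the trend
    statistics table, and the single-feature-vs-baseline comparison
    table.  Returns the written paths.  An empty sweep produces empty
    tables with a warning.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if not result.rows:
        warnings.warn("empty sweep result: writing empty report", stacklevel=2)
    written: dict[str, Path] = {}
    df = result.df
    for metric in METRICS:
        path = outdir / f"scatter_{metric}.tsv"
        df[["dataset", "combination", "n_features", metric]].to_csv(
            path, sep="\t", index=False
        )
        written[f"scatter_{metric}"] = path
    trends = trend_table(result) if result.rows else pd.DataFrame(
        columns=["metric", "rho", "p", "n"]
    )
    path = outdir / "trends.tsv"
    trends.to_csv(path, sep="\t", index=False)
    written["trends"] = path
    effects = single_feature_effects(result) if result.rows else pd.DataFrame(
        columns=["feature", "metric", "median_delta", "p", "p_bonferroni"]
    )
    path = outdir / "single_feature_effects.tsv"
    effects.to_csv(path, sep="\t", index=False)
    written["single_feature_effects"] = path
    if result.failures:
        path = outdir / "failures.tsv"
        pd.DataFrame(result.failures)[["dataset", "combination", "error"]].to_csv(
            path, sep="\t", index=False
        )
        written["failures"] = path
    return written
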