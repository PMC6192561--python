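"""Standard end-to-end experiments on synthetic studies.

These are the package's reference experiments: the feature-combination
sweep replicated over several synthetic worlds (master seeds), and a set
of degenerate controls (uninformative features, an oracle feature,
no-withholding robustness).  Both the test suite and the reproduction
script drive them through this module so the measured quantities are
computed exactly one way.

Problem sizes -- 5 co-elution datasets of 300 proteins x 50 fractions per
world, up to 3 sampled feature combinations per combination size, top-500
networks -- are the package's standard study conditions; they keep a full
five-world replication tractable on a single CPU while leaving every
trend well-powered (>= 100 networks per world).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from coelnet.classifier import CoComplexModel, derive_seed
from coelnet.elution import build_pair_features, filter_proteins, fit_gaussian_mixture
from coelnet.evaluation import (
    evaluate_network,
    filter_annotations,
    jaccard_index,
    neighbor_voting_auroc,
    robustness_jaccard,
)
from coelnet.genomic import FEATURE_KINDS, attach_external_features
from coelnet.stats import spearman_trend
from coelnet.sweep import (
    SweepConfig,
    SweepResult,
    enumerate_combinations,
    run_sweep,
    trend_table,
)
from coelnet.synthetic import (
    WorldConfig,
    simulate_genomic_feature,
    simulate_study_inputs,
)

__all__ = [
    "StudyRun",
    "run_standard_study",
    "replicate_trends",
    "gaussian_recovery_errors",
    "degenerate_controls",
]

N_DATASETS = 5
MAX_PER_SIZE = 3
TOP_N = 500
CUTOFF_YEAR = 2017


@dataclass
class StudyRun:
    """One synthetic world's sweep plus its trend statistics."""

    master_seed: int
    result: SweepResult
    trends: pd.DataFrame

    def trend(self, metric: str) -> tuple[float, float]:
        row = self.trends.set_index("metric").loc[metric]
        return float(row["rho"]), float(row["p"])


def _study_inputs(master_seed: int, config: WorldConfig | None = None):
    cfg = config or WorldConfig()
    cfg = replace(cfg, seed=derive_seed(master_seed, "world"))
    return cfg, simulate_study_inputs(cfg, n_datasets=N_DATASETS)


def run_standard_study(
    master_seed: int, config: WorldConfig | None = None
) -> StudyRun:
    """Run the full sweep for one synthetic world.

    Generates the world and its observables, computes the six
    dataset-derived features per co-elution dataset, runs the combination
    sweep (0-9 external features, up to 3 sampled combinations per size),
    and evaluates every network.
    """
    cfg, inputs = _study_inputs(master_seed, config)
    datasets = {
        did: build_pair_features(
            filter_proteins(matrix), seed=derive_seed(master_seed, "features", did)
        )
        for did, matrix in inputs["matrices"].items()
    }
    plan = enumerate_combinations(
        max_per_size=MAX_PER_SIZE, seed=derive_seed(master_seed, "plan")
    )
    sweep_config = SweepConfig(
        k_folds=10, top_n=TOP_N, cutoff_year=CUTOFF_YEAR, seed=master_seed
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = run_sweep(
            datasets,
            inputs["external"],
            inputs["complexes"],
            plan,
            inputs["annotations"],
            inputs["catalog"],
            inputs["publication_counts"],
            sweep_config,
        )
    return StudyRun(master_seed, result, trend_table(result))


def replicate_trends(master_seeds) -> list[StudyRun]:
    """Run the standard study for each master seed."""
    return [run_standard_study(s) for s in master_seeds]


# ---------------------------------------------------------------------------
# Controls


def gaussian_recovery_errors() -> dict[str, float]:
    """Deconvolution accuracy on noiseless planted profiles.

    Returns worst-case center and width errors over a grid of planted
    one-component profiles, and the worst center error for a well
    separated two-component profile.
    """
    x = np.arange(1, 51, dtype=float)
    mu_errs, sigma_errs = [], []
    for mu in (8.0, 12.0, 25.0, 40.0):
        for sigma in (1.5, 2.0, 3.0):
            fit = fit_gaussian_mixture(np.exp(-((x - mu) ** 2) / (2 * sigma**2)))
            comp = max(fit.components, key=lambda c: c[0])
            mu_errs.append(abs(comp[1] - mu))
            sigma_errs.append(abs(comp[2] - sigma))
    y = np.exp(-((x - 10.0) ** 2) / 8.0) + 0.8 * np.exp(-((x - 35.0) ** 2) / 8.0)
    fit2 = fit_gaussian_mixture(y)
    centers = sorted(c[1] for c in fit2.components)[:2]
    two_err = max(abs(centers[0] - 10.0), abs(centers[-1] - 35.0))
    return {
        "one_component_center_error": float(max(mu_errs)),
        "one_component_width_error": float(max(sigma_errs)),
        "two_component_center_error": float(two_err),
        "two_component_count": fit2.n_components,
    }


def degenerate_controls(master_seed: int = 101, n_datasets: int = 2) -> dict[str, float]:
    """Null and oracle controls on synthetic datasets.

    - ``uninformative_fc_delta``: shift in neighbor-voting AUROC when nine
      zero-informativeness features are attached, measured as the median
      over terms of the paired per-term AUROC difference (null minus
      baseline network), averaged over ``n_datasets`` datasets.  Pairing
      by term removes the between-term spread that dominates the plain
      difference of medians.  Should be ~0.
    - ``withhold0_jaccard_min``: minimum pairwise Jaccard between networks
      rebuilt with no withholding (must be 1).
    - ``oracle_feature_auroc``: held-out classification AUROC with a
      label-copy feature attached (must approach 1).
    """
    cfg, inputs = _study_inputs(master_seed)
    complexes = inputs["complexes"]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        null_cfg = replace(
            cfg, feature_informativeness=0.0, coverage_bias=0.0,
            spurious_association_rate=0.0,
        )
        null_features = {
            kind: simulate_genomic_feature(inputs["world"], kind, null_cfg)
            for kind in FEATURE_KINDS
        }
        deltas = []
        first_base = None
        first_fit_seed = None
        for did, matrix in list(inputs["matrices"].items())[:n_datasets]:
            base = build_pair_features(
                filter_proteins(matrix), seed=derive_seed(master_seed, "ctrl", did)
            )
            fit_seed = derive_seed(master_seed, "ctrl-fit", did)
            if first_base is None:
                first_base, first_fit_seed = base, fit_seed
            res0 = CoComplexModel(base, complexes).fit(k=10, seed=fit_seed)
            net0 = res0.top_n(TOP_N)
            per0, _ = neighbor_voting_auroc(
                net0, filter_annotations(inputs["annotations"], net0), seed=fit_seed
            )
            table_null = attach_external_features(
                base, list(FEATURE_KINDS), null_features
            )
            res_null = CoComplexModel(table_null, complexes).fit(k=10, seed=fit_seed)
            net_null = res_null.top_n(TOP_N)
            per_null, _ = neighbor_voting_auroc(
                net_null, filter_annotations(inputs["annotations"], net_null),
                seed=fit_seed,
            )
            shared = per0.index.intersection(per_null.index)
            deltas.append(float((per_null[shared] - per0[shared]).median()))

        # robustness without withholding must reproduce identical networks
        cocit = inputs["external"]["cocitation"]

        def pipeline(feature_table):
            table = attach_external_features(
                first_base, ["cocitation"], {"cocitation": feature_table}
            )
            res = CoComplexModel(table, complexes).fit(k=10, seed=first_fit_seed)
            return res.top_n(TOP_N)

        jaccards, _ = robustness_jaccard(
            pipeline, cocit, withhold=0.0, repeats=3, seed=first_fit_seed
        )

        # oracle feature: copy of the co-complex truth for labeled pairs
        labels = CoComplexModel(first_base, complexes).labels
        oracle = first_base.copy()
        oracle["oracle"] = labels.labels
        res_oracle = CoComplexModel(oracle, complexes).fit(k=10, seed=first_fit_seed)

    return {
        "uninformative_fc_delta": float(np.mean(deltas)),
        "withhold0_jaccard_min": float(min(jaccards)),
        "oracle_feature_auroc": float(res_oracle.held_out_auroc()),
    }
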