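"""Naive Bayes co-complex classification and network assembly.

Training labels come from a reference complex set (CORUM-style): protein
pairs co-occurring in a complex are positives, pairs whose members both
appear in the complex set but never together are negatives, and all other
pairs are unlabeled.  A naive Bayes classifier is trained on any feature
combination in stratified k-fold cross-validation; unlabeled pairs are
ranked by the median of their k fold scores, while labeled pairs receive
their held-out fold's score so that no pair is scored by a model that saw
its label.  Networks are assembled either as the top-N ranked pairs or by
thresholding at a target labeled-pair precision.

The modelling surface follows the statsmodels convention: a
:class:`CoComplexModel` is constructed from data and ``fit()`` returns a
:class:`CoComplexResults` carrying scores, diagnostics and a ``summary()``
table, with network assembly hanging off the results object.

Class-conditional densities are nonparametric: continuous features use a
binned kernel density estimate with Silverman's bandwidth, binary features
a Laplace-smoothed Bernoulli.  Missing feature values contribute a unit
likelihood ratio ("absence of evidence is not evidence").
"""

from __future__ import annotations

import io
import warnings
import zlib
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold

from coelnet.genomic import pair_key

__all__ = [
    "ComplexSet",
    "PairLabels",
    "label_pairs",
    "NaiveBayes",
    "naive_bayes_fit",
    "naive_bayes_score",
    "cross_validated_scores",
    "CoComplexModel",
    "CoComplexResults",
    "PredictedNetwork",
    "assemble_network_topN",
    "precision_curve",
    "assemble_network_precision",
    "TrainingInfeasibleError",
    "NetworkRejected",
]


class TrainingInfeasibleError(ValueError):
    """Raised when the labeled pairs cannot support training."""


class NetworkRejected(RuntimeError):
    """Raised when a precision-controlled network fails its constraints."""

    def __init__(self, reason: str):
        super().__init__(reason)
        self.reason = reason


class ComplexSet:
    """A reference set of protein complexes (complex id -> member set)."""

    def __init__(self, complexes: Mapping[str, Iterable[str]]):
        self.complexes: dict[str, frozenset[str]] = {}
        for cid, members in complexes.items():
            members = frozenset(members)
            if len(members) < 2:
                raise ValueError(f"complex {cid!r} has fewer than 2 members")
            self.complexes[str(cid)] = members

    def __len__(self) -> int:
        return len(self.complexes)

    def __getitem__(self, cid: str) -> frozenset[str]:
        return self.complexes[cid]

    def __iter__(self):
        return iter(self.complexes)

    @property
    def proteins(self) -> set[str]:
        out: set[str] = set()
        for members in self.complexes.values():
            out |= members
        return out

    def intra_pairs(self) -> set[tuple[str, str]]:
        """All unordered pairs co-occurring in at least one complex."""
        pairs: set[tuple[str, str]] = set()
        for members in self.complexes.values():
            ms = sorted(members)
            for i in range(len(ms)):
                for j in range(i + 1, len(ms)):
                    pairs.add((ms[i], ms[j]))
        return pairs

    def subset(self, ids: Iterable[str]) -> "ComplexSet":
        return ComplexSet({cid: self.complexes[cid] for cid in ids})

    # -- I/O (CORUM-like dialect) -------------------------------------------

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("complex_id\tmembers\n")
            for cid in sorted(self.complexes):
                fh.write(f"{cid}\t{';'.join(sorted(self.complexes[cid]))}\n")

    @classmethod
    def from_tsv(cls, path) -> "ComplexSet":
        df = pd.read_csv(path, sep="\t", dtype=str)
        return cls(
            {row.complex_id: row.members.split(";") for row in df.itertuples()}
        )


@dataclass
class PairLabels:
    """Per-row training labels: 1 positive, 0 negative, NaN unlabeled."""

    labels: pd.Series
    n_positive: int
    n_negative: int
    n_unlabeled: int


def label_pairs(table: pd.DataFrame, complexes: ComplexSet) -> PairLabels:
    """Label pair-table rows from a reference complex set.

    A pair is positive iff it co-occurs in some complex, negative iff both
    proteins appear in the complex set but never in the same complex, and
    unlabeled otherwise.  Raises :class:`TrainingInfeasibleError` when
    either class is empty.
    """
    intra = complexes.intra_pairs()
    universe = complexes.proteins
    a = table["id_a"].to_numpy(dtype=object)
    b = table["id_b"].to_numpy(dtype=object)
    labels = np.full(len(table), np.nan)
    for i in range(len(table)):
        p = pair_key(a[i], b[i])
        if p in intra:
            labels[i] = 1.0
        elif p[0] in universe and p[1] in universe:
            labels[i] = 0.0
    series = pd.Series(labels, index=table.index, name="label")
    n_pos = int((series == 1.0).sum())
    n_neg = int((series == 0.0).sum())
    if n_pos == 0 or n_neg == 0:
        raise TrainingInfeasibleError(
            f"training needs both classes (positives={n_pos}, negatives={n_neg})"
        )
    return PairLabels(series, n_pos, n_neg, int(series.isna().sum()))


# ---------------------------------------------------------------------------
# Naive Bayes with nonparametric class-conditional densities

_KDE_GRID = 256
_DENSITY_FLOOR = 1e-12


def _silverman(x: np.ndarray) -> float:
    n = len(x)
    sd = float(np.std(x))
    q75, q25 = np.percentile(x, [75, 25])
    iqr = float(q75 - q25)
    spread = min(sd, iqr / 1.34) if iqr > 0 else sd
    h = 0.9 * spread * n ** (-0.2)
    return h


@dataclass
class _BinaryFeature:
    p1_pos: float
    p1_neg: float

    def log_lr(self, x: np.ndarray) -> np.ndarray:
        lr1 = np.log(self.p1_pos) - np.log(self.p1_neg)
        lr0 = np.log(1 - self.p1_pos) - np.log(1 - self.p1_neg)
        out = np.where(x >= 0.5, lr1, lr0)
        return np.where(np.isnan(x), 0.0, out)


@dataclass
class _KdeFeature:
    grid: np.ndarray
    log_density_pos: np.ndarray
    log_density_neg: np.ndarray

    def log_lr(self, x: np.ndarray) -> np.ndarray:
        lp = np.interp(x, self.grid, self.log_density_pos)
        ln = np.interp(x, self.grid, self.log_density_neg)
        return np.where(np.isnan(x), 0.0, lp - ln)


def _binned_kde(x: np.ndarray, grid: np.ndarray, bandwidth: float) -> np.ndarray:
    """Gaussian KDE evaluated on a uniform grid via binning + smoothing."""
    binw = grid[1] - grid[0]
    edges = np.concatenate([grid - binw / 2, [grid[-1] + binw / 2]])
    counts, _ = np.histogram(x, bins=edges)
    density = gaussian_filter1d(counts.astype(float), sigma=bandwidth / binw, mode="constant")
    density /= max(density.sum() * binw, _DENSITY_FLOOR)
    return np.maximum(density, _DENSITY_FLOOR)


class NaiveBayes:
    """Naive Bayes over mixed binary / continuous features.

    Binary features (values within {0, 1}) use Laplace-smoothed Bernoulli
    likelihoods (alpha = 1); continuous features use class-conditional
    binned Gaussian KDEs with Silverman's bandwidth.  The posterior for
    the positive class assumes conditional independence with class priors
    taken from training frequencies; features missing for a given pair are
    skipped (unit likelihood ratio).
    """

    def __init__(self):
        self.features: dict[str, _BinaryFeature | _KdeFeature] = {}
        self.dropped: list[str] = []
        self.log_prior_ratio: float = 0.0
        self.prior_positive: float = 0.5

    def fit(self, X: pd.DataFrame, y: np.ndarray) -> "NaiveBayes":
        y = np.asarray(y, dtype=float)
        if set(np.unique(y)) - {0.0, 1.0}:
            raise ValueError("labels must be 0/1")
        n_pos = int((y == 1).sum())
        n_neg = int((y == 0).sum())
        if n_pos < 10 or n_neg < 10:
            raise TrainingInfeasibleError(
                f"need >= 10 examples per class (got {n_pos} / {n_neg})"
            )
        self.prior_positive = n_pos / (n_pos + n_neg)
        self.log_prior_ratio = float(np.log(n_pos) - np.log(n_neg))
        for col in X.columns:
            values = X[col].to_numpy(dtype=float)
            finite = values[~np.isnan(values)]
            if finite.size == 0 or np.unique(finite).size == 1:
                self.dropped.append(col)
                warnings.warn(f"dropping degenerate feature {col!r}", stacklevel=2)
                continue
            xp = values[(y == 1) & ~np.isnan(values)]
            xn = values[(y == 0) & ~np.isnan(values)]
            if xp.size == 0 or xn.size == 0:
                self.dropped.append(col)
                warnings.warn(
                    f"dropping feature {col!r}: unobserved in one class", stacklevel=2
                )
                continue
            if np.isin(finite, (0.0, 1.0)).all():
                self.features[col] = _BinaryFeature(
                    p1_pos=(xp.sum() + 1.0) / (xp.size + 2.0),
                    p1_neg=(xn.sum() + 1.0) / (xn.size + 2.0),
                )
            else:
                lo, hi = float(finite.min()), float(finite.max())
                h = max(_silverman(xp), _silverman(xn))
                if h <= 0:
                    h = max((hi - lo) * 1e-3, 1e-6)
                grid = np.linspace(lo - 3 * h, hi + 3 * h, _KDE_GRID)
                self.features[col] = _KdeFeature(
                    grid=grid,
                    log_density_pos=np.log(_binned_kde(xp, grid, h)),
                    log_density_neg=np.log(_binned_kde(xn, grid, h)),
                )
        return self

    def score(self, X: pd.DataFrame) -> np.ndarray:
        """Posterior probability of the positive class for each row."""
        log_odds = np.full(len(X), self.log_prior_ratio)
        for col, feat in self.features.items():
            log_odds += feat.log_lr(X[col].to_numpy(dtype=float))
        return 1.0 / (1.0 + np.exp(-log_odds))


def naive_bayes_fit(X: pd.DataFrame, y) -> NaiveBayes:
    """Fit a naive Bayes model on labeled feature rows."""
    return NaiveBayes().fit(X, np.asarray(y))


def naive_bayes_score(model: NaiveBayes, X: pd.DataFrame) -> np.ndarray:
    """Posterior positive-class probabilities under a fitted model."""
    return model.score(X)


# ---------------------------------------------------------------------------
# Cross-validated scoring


def cross_validated_scores(
    table: pd.DataFrame,
    labels: PairLabels,
    feature_columns: Sequence[str],
    k: int = 10,
    seed: int = 0,
    labeled_mode: str = "out_of_fold",
    classifier_factory=None,
) -> tuple[pd.Series, pd.Series]:
    """Score every pair by stratified k-fold cross-validation.

    Labeled pairs are partitioned into ``k`` stratified folds; each fold's
    model is trained on the remaining folds.  Unlabeled pairs receive the
    median of their ``k`` fold scores.  Labeled pairs receive, by default,
    the score of the one model that excluded them
    (``labeled_mode="out_of_fold"``); ``labeled_mode="median"`` instead
    gives them the median across all folds (note this lets k-1 models see
    the pair's label).

    Returns ``(scores, fold)`` where ``fold`` holds each labeled pair's
    held-out fold index (NaN for unlabeled pairs).
    """
    if labeled_mode not in ("out_of_fold", "median"):
        raise ValueError(f"unknown labeled_mode: {labeled_mode!r}")
    if classifier_factory is None:
        classifier_factory = NaiveBayes
    y = labels.labels.to_numpy(dtype=float)
    labeled = ~np.isnan(y)
    idx_labeled = np.flatnonzero(labeled)
    y_lab = y[labeled].astype(int)
    if k > min(labels.n_positive, labels.n_negative):
        raise ValueError("k exceeds the smaller class size")
    X = table[list(feature_columns)]
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed & 0x7FFFFFFF)
    all_scores = np.empty((len(table), k))
    fold_of = pd.Series(np.nan, index=table.index, name="fold")
    for f, (train_i, test_i) in enumerate(skf.split(np.zeros(len(y_lab)), y_lab)):
        rows = idx_labeled[train_i]
        model = classifier_factory().fit(X.iloc[rows], y[rows])
        all_scores[:, f] = model.score(X)
        fold_of.iloc[idx_labeled[test_i]] = f
    scores = np.median(all_scores, axis=1)
    if labeled_mode == "out_of_fold":
        fold_idx = fold_of.to_numpy()
        for i in idx_labeled:
            scores[i] = all_scores[i, int(fold_idx[i])]
    return pd.Series(scores, index=table.index, name="score"), fold_of


# ---------------------------------------------------------------------------
# Networks


class PredictedNetwork:
    """A ranked, scored edge list with assembly metadata.

    ``edges`` is a DataFrame with columns ``id_a``, ``id_b``, ``score``,
    ``rank`` (1-based, scores non-increasing).
    """

    def __init__(self, edges: pd.DataFrame, metadata: dict | None = None):
        edges = edges.reset_index(drop=True)
        if len(edges) and (np.diff(edges["score"].to_numpy()) > 1e-12).any():
            raise ValueError("edge scores must be non-increasing in rank")
        self.edges = edges
        self.metadata = dict(metadata or {})

    def __len__(self) -> int:
        return len(self.edges)

    @property
    def edge_set(self) -> set[tuple[str, str]]:
        return {
            pair_key(a, b)
            for a, b in zip(self.edges["id_a"], self.edges["id_b"])
        }

    @property
    def proteins(self) -> set[str]:
        return set(self.edges["id_a"]) | set(self.edges["id_b"])

    def degrees(self) -> pd.Series:
        return (
            pd.concat([self.edges["id_a"], self.edges["id_b"]])
            .value_counts()
            .sort_index()
            .rename("degree")
        )

    def graph(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.proteins)
        g.add_edges_from(self.edge_set)
        return g

    # -- I/O ----------------------------------------------------------------

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            for key, value in sorted(self.metadata.items()):
                fh.write(f"# {key}: {value}\n")
            self.edges.to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "PredictedNetwork":
        metadata = {}
        lines = []
        with open(path) as fh:
            for line in fh:
                if line.startswith("# "):
                    key, _, value = line[2:].rstrip("\n").partition(": ")
                    metadata[key] = value
                else:
                    lines.append(line)
        edges = pd.read_csv(io.StringIO("".join(lines)), sep="\t")
        return cls(edges, metadata)


def _ranked_edges(scored: pd.DataFrame) -> pd.DataFrame:
    """Sort by descending score, ties broken by lexicographic pair order."""
    out = scored.sort_values(
        ["score", "id_a", "id_b"], ascending=[False, True, True], kind="mergesort"
    ).reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out[["id_a", "id_b", "score", "rank"]]


def assemble_network_topN(
    scored: pd.DataFrame, n: int = 10000, metadata: dict | None = None
) -> PredictedNetwork:
    """Assemble the network of the N highest-scoring pairs.

    ``scored`` needs columns ``id_a``, ``id_b``, ``score``.  Boundary ties
    are broken by lexicographic pair order; if fewer than N pairs are
    available all are taken and the shortfall is flagged in the metadata.
    """
    ranked = _ranked_edges(scored.dropna(subset=["score"]))
    meta = dict(metadata or {})
    meta["assembly"] = f"top_{n}"
    if len(ranked) < n:
        meta["shortfall"] = n - len(ranked)
    return PredictedNetwork(ranked.head(n), meta)


def precision_curve(scores: np.ndarray, y: np.ndarray) -> pd.DataFrame:
    """Labeled-pair precision at every score threshold.

    Returns a DataFrame (``threshold``, ``tp``, ``fp``, ``precision``)
    over descending unique labeled scores, where precision at threshold t
    is TP / (TP + FP) among labeled pairs scoring >= t.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y, dtype=float)
    order = np.argsort(-scores, kind="mergesort")
    s = scores[order]
    t = y[order]
    tp = np.cumsum(t == 1)
    fp = np.cumsum(t == 0)
    last = np.r_[s[1:] != s[:-1], True]  # last occurrence of each unique score
    return pd.DataFrame(
        {
            "threshold": s[last],
            "tp": tp[last],
            "fp": fp[last],
            "precision": tp[last] / np.maximum(tp[last] + fp[last], 1),
        }
    )


def assemble_network_precision(
    scored: pd.DataFrame,
    labels: PairLabels,
    precision: float = 0.5,
    min_edges: int = 2000,
    metadata: dict | None = None,
) -> PredictedNetwork:
    """Assemble the largest network meeting a labeled-pair precision target.

    The threshold is the smallest labeled score t at which precision
    (among labeled pairs scoring >= t) reaches the target; the network
    contains every pair -- labeled or unlabeled -- scoring >= t.  Raises
    :class:`NetworkRejected` when the target is unreachable or the network
    has fewer than ``min_edges`` edges.
    """
    y = labels.labels.to_numpy(dtype=float)
    mask = ~np.isnan(y)
    curve = precision_curve(scored["score"].to_numpy()[mask], y[mask])
    feasible = curve[curve["precision"] >= precision]
    if feasible.empty:
        raise NetworkRejected(f"precision {precision} unreachable")
    threshold = float(feasible["threshold"].min())
    edges = scored[scored["score"] >= threshold]
    if len(edges) < min_edges:
        raise NetworkRejected(
            f"{len(edges)} edges at precision {precision} < min_edges={min_edges}"
        )
    meta = dict(metadata or {})
    meta["assembly"] = f"precision_{precision}"
    meta["threshold"] = threshold
    return PredictedNetwork(_ranked_edges(edges), meta)


# ---------------------------------------------------------------------------
# Model / results objects


class CoComplexModel:
    """Co-complex interaction model over a pair feature table.

    Parameters
    ----------
    pair_features : pandas.DataFrame
        Pair table with ``id_a``/``id_b`` and feature columns (the six
        dataset-derived features, plus any attached external columns).
    complexes : ComplexSet
        Reference complexes supplying training labels.
    feature_columns : sequence of str, optional
        Columns used by the classifier; defaults to every column other
        than the identifiers.

    Examples
    --------
    >>> model = CoComplexModel(features, corum)      # doctest: +SKIP
    >>> res = model.fit(k=10, seed=0)                # doctest: +SKIP
    >>> net = res.top_n(10000)                       # doctest: +SKIP
    """

    def __init__(
        self,
        pair_features: pd.DataFrame,
        complexes: ComplexSet,
        feature_columns: Sequence[str] | None = None,
        classifier_factory=None,
    ):
        self.pair_features = pair_features.reset_index(drop=True)
        self.complexes = complexes
        if feature_columns is None:
            feature_columns = [
                c for c in pair_features.columns if c not in ("id_a", "id_b")
            ]
        self.feature_columns = list(feature_columns)
        # pluggable classifier: any zero-argument factory whose product has
        # fit(X, y) -> self and score(X) -> array of positive-class scores
        self.classifier_factory = classifier_factory
        self.labels = label_pairs(self.pair_features, complexes)

    def fit(
        self, k: int = 10, seed: int = 0, labeled_mode: str = "out_of_fold"
    ) -> "CoComplexResults":
        scores, folds = cross_validated_scores(
            self.pair_features,
            self.labels,
            self.feature_columns,
            k=k,
            seed=seed,
            labeled_mode=labeled_mode,
            classifier_factory=self.classifier_factory,
        )
        return CoComplexResults(self, scores, folds, k=k, seed=seed)


class CoComplexResults:
    """Cross-validated co-complex scores and network assembly."""

    def __init__(
        self,
        model: CoComplexModel,
        scores: pd.Series,
        folds: pd.Series,
        k: int,
        seed: int,
    ):
        self.model = model
        self.scores = scores
        self.folds = folds
        self.k = k
        self.seed = seed

    @property
    def scored_pairs(self) -> pd.DataFrame:
        out = self.model.pair_features[["id_a", "id_b"]].copy()
        out["score"] = self.scores
        return out

    def held_out_auroc(self) -> float:
        """AUROC separating positives from negatives on held-out scores."""
        y = self.model.labels.labels.to_numpy(dtype=float)
        mask = ~np.isnan(y)
        s = self.scores.to_numpy()[mask]
        t = y[mask]
        ranks = rankdata(s)
        n1 = (t == 1).sum()
        n0 = (t == 0).sum()
        u = ranks[t == 1].sum() - n1 * (n1 + 1) / 2
        return float(u / (n1 * n0))

    def top_n(self, n: int = 10000) -> PredictedNetwork:
        return assemble_network_topN(self.scored_pairs, n, self._meta())

    def at_precision(
        self, precision: float = 0.5, min_edges: int = 2000
    ) -> PredictedNetwork:
        return assemble_network_precision(
            self.scored_pairs, self.model.labels, precision, min_edges, self._meta()
        )

    def precision_curve(self) -> pd.DataFrame:
        y = self.model.labels.labels.to_numpy(dtype=float)
        mask = ~np.isnan(y)
        return precision_curve(self.scores.to_numpy()[mask], y[mask])

    def _meta(self) -> dict:
        return {
            "features": ",".join(self.model.feature_columns),
            "k_folds": self.k,
            "seed": self.seed,
        }

    def summary(self) -> str:
        lab = self.model.labels
        lines = [
            "Co-complex naive Bayes classifier",
            "=" * 40,
            f"pairs scored:        {len(self.scores)}",
            f"positive pairs:      {lab.n_positive}",
            f"negative pairs:      {lab.n_negative}",
            f"unlabeled pairs:     {lab.n_unlabeled}",
            f"features:            {len(self.model.feature_columns)}",
            f"cv folds:            {self.k}",
            f"held-out AUROC:      {self.held_out_auroc():.4f}",
        ]
        return "\n".join(lines)


def derive_seed(master: int, *parts) -> int:
    """Derive a deterministic stage seed below 2^31 from a master seed."""
    digest = zlib.crc32(repr((master, *parts)).encode())
    return digest & 0x7FFFFFFF
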