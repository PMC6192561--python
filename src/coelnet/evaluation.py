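"""Evaluation outcomes for predicted interaction networks.

Five outcome families quantify what a network is good for and what it is
biased by:

1. **Functional connectivity** -- guilt-by-association protein function
   prediction: each protein is scored for a term by the fraction of its
   network neighbors annotated with that term, in n-fold cross-validation
   over annotations; a term's AUROC measures recovery of hidden
   annotations, and the network is summarized by the median AUROC over
   terms.
2. **Novelty** -- the fraction of network edges absent from a catalog of
   known interactions.
3. **Time-split validation** -- among edges unknown before a cutoff year,
   the fraction subsequently rediscovered, estimating the true-positive
   rate among putative novel interactions.
4. **Study bias** -- the Spearman correlation between each protein's
   network degree and its publication count.
5. **Topology / robustness** -- the global clustering coefficient
   (transitivity), and the Jaccard stability of networks rebuilt after
   randomly withholding part of an evidence table.

Undefined metrics propagate as NaN, never as zeros.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from typing import Callable, Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import rankdata, spearmanr

from coelnet.classifier import PredictedNetwork
from coelnet.genomic import InteractionCatalog, pair_key

__all__ = [
    "AnnotationTable",
    "EvaluationReport",
    "DEFAULT_DROP_CODES",
    "filter_annotations",
    "neighbor_voting_auroc",
    "novelty_fraction",
    "timesplit_validation_rate",
    "degree_publication_bias",
    "global_clustering_coefficient",
    "jaccard_index",
    "robustness_jaccard",
    "withhold_entries",
    "evaluate_network",
    "write_publication_counts",
    "read_publication_counts",
]

#: GO evidence codes treated as unreliable for function prediction.
DEFAULT_DROP_CODES = frozenset({"ND", "IPI", "IEA", "NAS"})


class AnnotationTable:
    """Protein -> term annotations with per-row evidence codes.

    Backed by a DataFrame with columns ``protein``, ``term``,
    ``evidence_code`` (GAF-like).  Terms are flat labels; no ontology
    graph propagation is performed.
    """

    def __init__(self, df: pd.DataFrame):
        missing = {"protein", "term", "evidence_code"} - set(df.columns)
        if missing:
            raise ValueError(f"annotation table missing columns: {sorted(missing)}")
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def terms(self) -> list[str]:
        return sorted(self.df["term"].unique())

    def assignments(self) -> pd.DataFrame:
        """Distinct (protein, term) assignments."""
        return self.df[["protein", "term"]].drop_duplicates().reset_index(drop=True)

    def proteins_for(self, term: str) -> set[str]:
        return set(self.df.loc[self.df["term"] == term, "protein"])

    def to_tsv(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "AnnotationTable":
        return cls(pd.read_csv(path, sep="\t", dtype=str))


def filter_annotations(
    ann: AnnotationTable,
    network: PredictedNetwork,
    min_frac: float = 0.005,
    max_frac: float = 0.05,
    drop_codes: frozenset[str] = DEFAULT_DROP_CODES,
) -> AnnotationTable:
    """Restrict annotations to reliable, informative terms on a network.

    Drops (protein, term) assignments supported *only* by the evidence
    codes in ``drop_codes``, restricts to the network's proteins, and
    keeps terms annotating between ``min_frac`` and ``max_frac``
    (inclusive) of the network's proteins -- excluding very broad and very
    specific terms.
    """
    proteins = network.proteins
    df = ann.df[ann.df["protein"].isin(proteins)]
    reliable = (
        df.groupby(["protein", "term"])["evidence_code"]
        .apply(lambda codes: any(c not in drop_codes for c in codes))
        .rename("keep")
        .reset_index()
    )
    df = df.merge(reliable, on=["protein", "term"])
    df = df[df["keep"]].drop(columns="keep")
    n = len(proteins)
    sizes = df.groupby("term")["protein"].nunique()
    ok_terms = sizes[(sizes >= min_frac * n) & (sizes <= max_frac * n)].index
    out = df[df["term"].isin(ok_terms)].reset_index(drop=True)
    if out.empty:
        warnings.warn("no terms survive annotation filtering", stacklevel=2)
    return AnnotationTable(out)


def _auroc_from_scores(pos_scores: np.ndarray, neg_scores: np.ndarray) -> float:
    """Rank-statistic AUROC with mid-ranks for ties."""
    scores = np.concatenate([pos_scores, neg_scores])
    ranks = rankdata(scores)
    n1, n0 = len(pos_scores), len(neg_scores)
    u = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    return float(u / (n1 * n0))


def neighbor_voting_auroc(
    network: PredictedNetwork,
    ann: AnnotationTable,
    n_folds: int = 3,
    seed: int = 0,
) -> tuple[pd.Series, float]:
    """Guilt-by-association function prediction accuracy, per term.

    Annotation assignments are split into ``n_folds`` random folds.  Per
    fold and term, each protein's score is the fraction of its network
    neighbors annotated with the term in the training folds; the AUROC
    compares the fold's hidden positives against proteins never annotated
    with the term.  A term's AUROC is the mean over folds with at least
    one hidden positive; folds without one are skipped.  Returns the
    per-term AUROC series and its median.
    """
    proteins = sorted(network.proteins)
    index = {p: i for i, p in enumerate(proteins)}
    n = len(proteins)
    A = np.zeros((n, n))
    for a, b in network.edge_set:
        A[index[a], index[b]] = 1.0
        A[index[b], index[a]] = 1.0
    degree = A.sum(axis=1)

    assign = ann.assignments()
    assign = assign[assign["protein"].isin(index)]
    terms = sorted(assign["term"].unique())
    tindex = {t: j for j, t in enumerate(terms)}
    if not terms:
        return pd.Series(dtype=float), float("nan")
    rows = assign["protein"].map(index).to_numpy()
    cols = assign["term"].map(tindex).to_numpy()

    rng = np.random.default_rng(seed)
    fold_of = rng.integers(0, n_folds, size=len(assign))
    Y_full = np.zeros((n, len(terms)))
    Y_full[rows, cols] = 1.0

    aurocs = np.full((len(terms), n_folds), np.nan)
    for f in range(n_folds):
        train = fold_of != f
        Y_train = np.zeros_like(Y_full)
        Y_train[rows[train], cols[train]] = 1.0
        with np.errstate(invalid="ignore", divide="ignore"):
            S = (A @ Y_train) / degree[:, None]
        S = np.nan_to_num(S)
        for t in range(len(terms)):
            hidden = (Y_full[:, t] == 1) & (Y_train[:, t] == 0)
            negative = Y_full[:, t] == 0
            # a fold needs hidden positives to score, training annotations
            # to vote with, and negatives to rank against
            if hidden.sum() == 0 or negative.sum() == 0 or Y_train[:, t].sum() == 0:
                continue
            aurocs[t, f] = _auroc_from_scores(S[hidden, t], S[negative, t])

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        per_term = pd.Series(np.nanmean(aurocs, axis=1), index=terms, name="auroc")
    per_term = per_term.dropna()
    median = float(per_term.median()) if len(per_term) else float("nan")
    return per_term, median


def novelty_fraction(
    network: PredictedNetwork,
    catalog: InteractionCatalog,
    cutoff_year: int | None = None,
) -> float:
    """Fraction of network edges absent from the known-interaction catalog.

    With a cutoff year, only records dated strictly before the cutoff
    count as known.  Undefined (NaN) for an empty network.
    """
    edges = network.edge_set
    if not edges:
        return float("nan")
    known = edges & catalog.pairs_known_before(cutoff_year)
    return 1.0 - len(known) / len(edges)


def timesplit_validation_rate(
    network: PredictedNetwork,
    catalog: InteractionCatalog,
    cutoff_year: int,
    exclude_pmids: Iterable[str] = (),
) -> float:
    """Rediscovery rate of putatively novel edges after a time split.

    Records supported only by ``exclude_pmids`` (circular evidence, e.g.
    the publications of the analyzed experiments themselves) are removed.
    An edge is novel if no remaining record predates the cutoff year, and
    validated if some record is dated in or after the cutoff.  Undefined
    (NaN) when no edge is novel.
    """
    cat = catalog.without_pmids(exclude_pmids) if exclude_pmids else catalog
    edges = network.edge_set
    novel = edges - cat.pairs_known_before(cutoff_year)
    if not novel:
        return float("nan")
    validated = novel & cat.pairs_discovered_from(cutoff_year)
    return len(validated) / len(novel)


def degree_publication_bias(
    network: PredictedNetwork, publication_counts: pd.Series
) -> float:
    """Spearman correlation between network degree and publication count.

    Proteins without a recorded count contribute 0 with a warning.
    Undefined with fewer than 3 network proteins or a constant count
    vector.
    """
    degrees = network.degrees()
    if len(degrees) < 3:
        return float("nan")
    pubs = degrees.index.map(
        lambda p: publication_counts.get(p, np.nan)
    ).to_numpy(dtype=float)
    if np.isnan(pubs).any():
        warnings.warn(
            f"{int(np.isnan(pubs).sum())} network proteins lack publication "
            "counts; treated as 0",
            stacklevel=2,
        )
        pubs = np.nan_to_num(pubs)
    if np.all(pubs == pubs[0]) or degrees.nunique() == 1:
        warnings.warn("zero variance in bias inputs; correlation undefined", stacklevel=2)
        return float("nan")
    rho, _ = spearmanr(degrees.to_numpy(), pubs)
    return float(rho)


def global_clustering_coefficient(network: PredictedNetwork) -> float:
    """Global clustering coefficient: 3 x triangles / connected triples.

    The probability that two proteins sharing a neighbor are themselves
    connected; 0 when the network has no connected triples.
    """
    return float(nx.transitivity(network.graph()))


def jaccard_index(net_a: PredictedNetwork, net_b: PredictedNetwork) -> float:
    """Edge-set Jaccard index; undefined when both networks are empty."""
    ea, eb = net_a.edge_set, net_b.edge_set
    union = ea | eb
    if not union:
        return float("nan")
    return len(ea & eb) / len(union)


def withhold_entries(
    table: pd.DataFrame,
    fraction: float,
    rng: np.random.Generator,
    unit: str = "pair",
) -> pd.DataFrame:
    """Randomly withhold part of an evidence table.

    ``unit="pair"`` drops a uniformly random fraction of rows (pair-native
    evidence such as co-citation scores or interolog indicators);
    ``unit="protein"`` instead samples a fraction of the proteins
    appearing in the table and drops every row involving them
    (protein-derived evidence such as expression profiles or domain
    assignments).
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    if fraction == 0.0:
        return table
    if unit == "pair":
        n_drop = int(round(fraction * len(table)))
        drop = rng.choice(len(table), size=n_drop, replace=False)
        return table.drop(table.index[drop]).reset_index(drop=True)
    if unit == "protein":
        proteins = sorted(set(table["id_a"]) | set(table["id_b"]))
        n_drop = int(round(fraction * len(proteins)))
        dropped = set(rng.choice(proteins, size=n_drop, replace=False))
        keep = ~(table["id_a"].isin(dropped) | table["id_b"].isin(dropped))
        return table[keep].reset_index(drop=True)
    raise ValueError(f"unknown withholding unit: {unit!r}")


def robustness_jaccard(
    pipeline: Callable[[pd.DataFrame], PredictedNetwork],
    feature_table: pd.DataFrame,
    withhold: float = 0.2,
    repeats: int = 5,
    seed: int = 0,
    unit: str = "pair",
) -> tuple[list[float], float]:
    """Network stability under random withholding of one evidence table.

    Per repeat, a random ``withhold`` fraction of the table's entries is
    removed, the network is rebuilt via ``pipeline``, and all pairwise
    Jaccard indices between the ``repeats`` rebuilt networks are returned
    along with their median.
    """
    networks = []
    for r in range(repeats):
        rng = np.random.default_rng([seed & 0x7FFFFFFF, r])
        networks.append(pipeline(withhold_entries(feature_table, withhold, rng, unit)))
    jaccards = [
        jaccard_index(networks[i], networks[j])
        for i in range(repeats)
        for j in range(i + 1, repeats)
    ]
    return jaccards, float(np.median(jaccards))


# ---------------------------------------------------------------------------
# Reports


@dataclass
class EvaluationReport:
    """All standard outcomes for one predicted network."""

    median_auroc: float = float("nan")
    n_terms: int = 0
    novelty_fraction: float = float("nan")
    validation_rate: float = float("nan")
    bias_rho: float = float("nan")
    clustering_coefficient: float = float("nan")
    n_edges: int = 0
    n_proteins: int = 0
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)

    def to_tsv(self, path, network_id: str = "network") -> None:
        """Write one (network, metric, value) row per metric."""
        metrics = {
            k: v
            for k, v in self.to_dict().items()
            if k != "provenance"
        }
        rows = [
            {"network": network_id, "metric": k, "value": v}
            for k, v in metrics.items()
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def evaluate_network(
    network: PredictedNetwork,
    annotations: AnnotationTable,
    catalog: InteractionCatalog,
    publication_counts: pd.Series,
    cutoff_year: int | None = None,
    exclude_pmids: Iterable[str] = (),
    n_folds: int = 3,
    seed: int = 0,
) -> EvaluationReport:
    """Compute the full evaluation battery for one network."""
    filtered = filter_annotations(annotations, network)
    per_term, median = neighbor_voting_auroc(network, filtered, n_folds=n_folds, seed=seed)
    report = EvaluationReport(
        median_auroc=median,
        n_terms=len(per_term),
        novelty_fraction=novelty_fraction(network, catalog, cutoff_year),
        bias_rho=degree_publication_bias(network, publication_counts),
        clustering_coefficient=global_clustering_coefficient(network),
        n_edges=len(network),
        n_proteins=len(network.proteins),
        provenance=dict(network.metadata, cutoff_year=cutoff_year, seed=seed),
    )
    if cutoff_year is not None:
        report.validation_rate = timesplit_validation_rate(
            network, catalog, cutoff_year, exclude_pmids
        )
    return report


def write_publication_counts(counts: pd.Series, path) -> None:
    counts.rename("publication_count").rename_axis("protein").to_csv(path, sep="\t")


def read_publication_counts(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df["publication_count"]
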