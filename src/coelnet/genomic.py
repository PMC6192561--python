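"""External genomic evidence at the protein-pair level.

Co-elution classifiers are frequently supplemented with evidence of
functional association from public genomic resources.  This module builds
the nine such features used throughout the package:

- ``coexpression``: Pearson correlation of mRNA expression profiles.
- ``phylogenetic``: Pearson correlation of binarized ortholog
  presence/absence profiles across species.
- ``domain``: indicator of a known domain-domain interaction between the
  two proteins' domain sets.
- ``cocitation``, ``fusion``, ``neighborhood``: precomputed association
  scores in [0, 1], consumed from prepared tables.
- ``interolog_LC``, ``interolog_Y2H``, ``interolog_IP``: indicators of a
  reported interaction between orthologs in *another* species, curated
  from small-scale literature (LC), yeast two-hybrid (Y2H) or
  co-immunoprecipitation (IP) experiments.

All pair tables are keyed on the lexicographically sorted pair and are
symmetric in the two identifiers.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from coelnet.elution import sort_pair_table

__all__ = [
    "FEATURE_KINDS",
    "BINARY_KINDS",
    "FeatureSpec",
    "InteractionRecord",
    "InteractionCatalog",
    "coexpression_scores",
    "phylogenetic_profile_scores",
    "domain_interaction_indicator",
    "interolog_indicator",
    "load_pair_score_table",
    "attach_external_features",
    "pair_key",
]

#: The nine external feature kinds, in canonical order.
FEATURE_KINDS = (
    "coexpression",
    "phylogenetic",
    "domain",
    "cocitation",
    "fusion",
    "neighborhood",
    "interolog_LC",
    "interolog_Y2H",
    "interolog_IP",
)

#: Kinds emitting 0/1 indicators rather than continuous scores.
BINARY_KINDS = frozenset(
    {"domain", "interolog_LC", "interolog_Y2H", "interolog_IP"}
)

#: Publications reporting at most this many interactions count as small-scale.
SMALL_SCALE_MAX_PPIS = 25


def pair_key(a: str, b: str) -> tuple[str, str]:
    """Order-normalized pair key."""
    return (a, b) if a <= b else (b, a)


@dataclass(frozen=True)
class FeatureSpec:
    """One external feature within a combination."""

    name: str
    source: str | None = None
    parameters: dict = field(default_factory=dict, compare=False)

    def __post_init__(self):
        if self.name not in FEATURE_KINDS:
            raise ValueError(f"unknown feature kind: {self.name!r}")


# ---------------------------------------------------------------------------
# Interaction catalogs


@dataclass
class InteractionRecord:
    """One time-stamped, evidence-coded known interaction."""

    id_a: str
    id_b: str
    method: str = ""
    pmids: tuple[str, ...] = ()
    years: tuple[int, ...] = ()
    species: str = ""

    def __post_init__(self):
        if self.id_a == self.id_b:
            raise ValueError("self-interactions are not modelled")
        self.id_a, self.id_b = pair_key(self.id_a, self.id_b)
        self.pmids = tuple(self.pmids)
        self.years = tuple(int(y) for y in self.years)
        if self.pmids and not self.years:
            raise ValueError("records with publications must carry years")

    @property
    def pair(self) -> tuple[str, str]:
        return (self.id_a, self.id_b)

    @property
    def first_year(self) -> int | None:
        return min(self.years) if self.years else None


class InteractionCatalog:
    """A multiset of known-interaction records, indexed by pair and year.

    Pair queries are insensitive to identifier order.  "Earliest year"
    semantics are used for discovery dates: a pair counts as known before a
    cutoff if any of its records carries a year strictly before the cutoff.
    """

    def __init__(self, records: Iterable[InteractionRecord]):
        self.records: list[InteractionRecord] = list(records)
        self._by_pair: dict[tuple[str, str], list[InteractionRecord]] = {}
        for rec in self.records:
            self._by_pair.setdefault(rec.pair, []).append(rec)

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, pair) -> bool:
        return pair_key(*pair) in self._by_pair

    @property
    def pairs(self) -> set[tuple[str, str]]:
        return set(self._by_pair)

    def records_for(self, a: str, b: str) -> list[InteractionRecord]:
        return list(self._by_pair.get(pair_key(a, b), []))

    def pairs_known_before(self, cutoff_year: int | None) -> set[tuple[str, str]]:
        """Pairs with at least one record dated strictly before the cutoff.

        ``cutoff_year=None`` places no restriction (all catalogued pairs).
        """
        if cutoff_year is None:
            return self.pairs
        return {
            p
            for p, recs in self._by_pair.items()
            if any(y < cutoff_year for r in recs for y in r.years)
        }

    def pairs_discovered_from(self, cutoff_year: int) -> set[tuple[str, str]]:
        """Pairs with at least one record dated in or after the cutoff year."""
        return {
            p
            for p, recs in self._by_pair.items()
            if any(y >= cutoff_year for r in recs for y in r.years)
        }

    def without_pmids(self, pmids: Iterable[str]) -> "InteractionCatalog":
        """Drop records supported *only* by the given publications."""
        drop = set(pmids)
        kept = [
            r
            for r in self.records
            if not r.pmids or not set(r.pmids) <= drop
        ]
        return InteractionCatalog(kept)

    def publication_sizes(self) -> dict[str, int]:
        """Number of distinct catalogued pairs supported by each publication."""
        pairs_by_pmid: dict[str, set[tuple[str, str]]] = {}
        for rec in self.records:
            for pmid in rec.pmids:
                pairs_by_pmid.setdefault(pmid, set()).add(rec.pair)
        return {pmid: len(ps) for pmid, ps in pairs_by_pmid.items()}

    # -- I/O ----------------------------------------------------------------

    def to_tsv(self, path) -> None:
        rows = [
            {
                "id_a": r.id_a,
                "id_b": r.id_b,
                "method": r.method,
                "pmids": ";".join(r.pmids),
                "years": ";".join(str(y) for y in r.years),
                "species": r.species,
            }
            for r in self.records
        ]
        pd.DataFrame(
            rows, columns=["id_a", "id_b", "method", "pmids", "years", "species"]
        ).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "InteractionCatalog":
        df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
        records = [
            InteractionRecord(
                id_a=row.id_a,
                id_b=row.id_b,
                method=row.method,
                pmids=tuple(p for p in row.pmids.split(";") if p),
                years=tuple(int(y) for y in row.years.split(";") if y),
                species=row.species,
            )
            for row in df.itertuples()
        ]
        return cls(records)


# ---------------------------------------------------------------------------
# Feature construction


def _correlation_pairs(profiles: pd.DataFrame, degenerate_mask: np.ndarray) -> pd.DataFrame:
    ids = np.array(profiles.index, dtype=object)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(profiles.to_numpy(dtype=float))
    corr = np.clip(corr, -1.0, 1.0)
    corr[degenerate_mask, :] = np.nan
    corr[:, degenerate_mask] = np.nan
    iu, ju = np.triu_indices(len(ids), k=1)
    table = pd.DataFrame(
        {"id_a": ids[iu], "id_b": ids[ju], "score": corr[iu, ju]}
    ).dropna(subset=["score"])
    return sort_pair_table(table)


def coexpression_scores(expression: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Pearson correlation of expression profiles.

    ``expression`` is a genes x samples table of normalized expression
    values (at least 3 samples).  Genes with zero variance yield missing
    scores and are omitted from the output.
    """
    if expression.shape[1] < 3:
        raise ValueError("coexpression needs at least 3 samples")
    values = expression.to_numpy(dtype=float)
    degenerate = values.std(axis=1) == 0
    return _correlation_pairs(expression, degenerate)


def phylogenetic_profile_scores(presence: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Pearson correlation of binary presence/absence profiles.

    ``presence`` is a proteins x species 0/1 table.  All-present or
    all-absent profiles have no variance and yield missing scores.
    """
    if presence.shape[1] < 2:
        raise ValueError("phylogenetic profiles need at least 2 species")
    values = presence.to_numpy(dtype=float)
    if not np.isin(values, (0.0, 1.0)).all():
        raise ValueError("presence/absence table must be binary")
    degenerate = values.std(axis=1) == 0
    return _correlation_pairs(presence, degenerate)


def domain_interaction_indicator(
    domains: Mapping[str, set],
    ddi: Iterable[tuple[str, str]],
) -> pd.DataFrame:
    """Indicator of a known domain-domain interaction for each protein pair.

    ``indicator(a, b) = 1`` iff some domain of ``a`` and some domain of
    ``b`` form an unordered pair in the domain-domain interaction list
    (self-pairs allowed).  All pairs of proteins in ``domains`` are
    emitted.
    """
    ddi_set = {frozenset(p) for p in ddi}
    proteins = sorted(domains)
    rows = []
    for a, b in itertools.combinations(proteins, 2):
        hit = any(
            frozenset((da, db)) in ddi_set
            for da in domains[a]
            for db in domains[b]
        )
        rows.append({"id_a": a, "id_b": b, "score": 1.0 if hit else 0.0})
    return sort_pair_table(pd.DataFrame(rows, columns=["id_a", "id_b", "score"]))


def _record_matches_class(
    record: InteractionRecord, method_class: str, pub_sizes: dict[str, int]
) -> bool:
    method = record.method.lower()
    if method_class == "Y2H":
        return "two hybrid" in method
    if method_class == "IP":
        return "coimmunoprecipitation" in method
    if method_class == "LC":
        return any(
            pub_sizes.get(pmid, 0) <= SMALL_SCALE_MAX_PPIS for pmid in record.pmids
        )
    raise ValueError(f"unknown interolog class: {method_class!r}")


def interolog_indicator(
    catalog: InteractionCatalog,
    method_class: str,
    orthologs: Mapping[str, str],
    exclude_species: str,
    pairs: Sequence[tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """Interolog evidence indicators from a cross-species catalog.

    A focal-species pair receives indicator 1 iff some orthologous pair,
    recorded in a species other than ``exclude_species``, carries evidence
    of the requested class: Y2H (method contains "two hybrid"), IP (method
    contains "coimmunoprecipitation"), or LC (supported by a small-scale
    publication reporting at most 25 catalogued interactions).  Method
    matching is case-insensitive substring search.

    ``orthologs`` maps catalog-species identifiers to focal identifiers;
    records with an unmapped protein contribute nothing.  When ``pairs``
    is given, a full 0/1 column over those pairs is returned; otherwise
    only the positive pairs are emitted.
    """
    pub_sizes = catalog.publication_sizes() if method_class == "LC" else {}
    positive: set[tuple[str, str]] = set()
    for rec in catalog.records:
        if rec.species == exclude_species:
            continue
        if not _record_matches_class(rec, method_class, pub_sizes):
            continue
        a = orthologs.get(rec.id_a)
        b = orthologs.get(rec.id_b)
        if a is None or b is None or a == b:
            continue
        positive.add(pair_key(a, b))
    if pairs is None:
        rows = [{"id_a": a, "id_b": b, "score": 1.0} for a, b in sorted(positive)]
    else:
        rows = [
            {
                "id_a": pair_key(a, b)[0],
                "id_b": pair_key(a, b)[1],
                "score": 1.0 if pair_key(a, b) in positive else 0.0,
            }
            for a, b in pairs
        ]
    return sort_pair_table(pd.DataFrame(rows, columns=["id_a", "id_b", "score"]))


def load_pair_score_table(path, kind: str) -> pd.DataFrame:
    """Load a prepared (id_a, id_b, score) table for a precomputed feature.

    ``kind`` must be one of ``cocitation``, ``fusion`` or ``neighborhood``.
    Scores must lie in [0, 1]; malformed rows raise with their line number.
    Duplicate pairs (in either order) are resolved by the maximum score.
    """
    if kind not in {"cocitation", "fusion", "neighborhood"}:
        raise ValueError(f"not a precomputed score kind: {kind!r}")
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if lineno == 1 and parts[:2] == ["id_a", "id_b"]:
                continue  # optional header
            if len(parts) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 columns, got {len(parts)}")
            a, b, raw = parts
            try:
                score = float(raw)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed score {raw!r}") from exc
            if not 0.0 <= score <= 1.0:
                raise ValueError(f"{path}:{lineno}: score {score} outside [0, 1]")
            a, b = pair_key(a, b)
            rows.append({"id_a": a, "id_b": b, "score": score})
    if not rows:
        return pd.DataFrame(columns=["id_a", "id_b", "score"])
    table = pd.DataFrame(rows)
    table = table.groupby(["id_a", "id_b"], as_index=False)["score"].max()
    return sort_pair_table(table)


def attach_external_features(
    table: pd.DataFrame,
    combination: Sequence[FeatureSpec | str],
    feature_tables: Mapping[str, pd.DataFrame],
) -> pd.DataFrame:
    """Attach a combination of external feature columns to a pair table.

    Each feature adds one column named after its kind; pairs absent from a
    feature's table get a missing value.  The dataset-derived columns are
    unchanged, and an empty combination returns the table unmodified.
    """
    names = [c.name if isinstance(c, FeatureSpec) else c for c in combination]
    if len(set(names)) != len(names):
        raise ValueError("duplicate feature in combination")
    out = table.copy()
    for name in names:
        if name not in FEATURE_KINDS:
            raise ValueError(f"unknown feature kind: {name!r}")
        feat = feature_tables[name]
        col = feat.rename(columns={"score": name})[["id_a", "id_b", name]]
        out = out.merge(col, on=["id_a", "id_b"], how="left")
    return out
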