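"""Synthetic co-elution worlds with controllable bias and informativeness.

This module generates a complete ground-truth "world" -- protein
complexes, true interactions and a latent per-protein *study intensity*
(how intensively a protein has been studied) -- plus every observable the
pipeline consumes:

- co-elution chromatograms (Gaussian peaks at complex positions plus
  noise and missingness),
- the nine external genomic feature tables, with controllable
  informativeness and coverage bias toward well-studied proteins,
- a year-stamped known-interaction catalog whose discovery process is
  biased toward well-studied proteins,
- GO-like term annotations and per-protein publication counts.

Two structural layers matter.  *Complexes* define physical co-complex
membership: true interactions are exactly the intra-complex pairs, and
only complexes co-elute.  Each complex sits inside a *functional module*
together with a few associated-but-not-complexed proteins; external
genomic features and annotations follow modules, reflecting that
functional association is broader than physical interaction.  Setting
``module_extra_proteins=0`` (and one complex per module) collapses the
two layers, so that feature elevation exactly tracks co-complex status.

Fixed seeds give bit-identical outputs; each observable draws from its
own seed stream so generation order does not matter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from coelnet.classifier import ComplexSet
from coelnet.elution import ElutionMatrix, sort_pair_table
from coelnet.evaluation import AnnotationTable
from coelnet.genomic import (
    BINARY_KINDS,
    FEATURE_KINDS,
    InteractionCatalog,
    InteractionRecord,
)

__all__ = [
    "WorldConfig",
    "SyntheticWorld",
    "generate_world",
    "simulate_elution",
    "simulate_genomic_feature",
    "simulate_interaction_catalog",
    "simulate_annotations",
    "simulate_publication_counts",
    "simulate_study_inputs",
]

# seed-stream labels, one per observable
_STREAMS = {
    "world": 11,
    "elution": 23,
    "feature": 37,
    "catalog": 53,
    "annotation": 67,
    "publications": 79,
}

#: How often a functional association leaves a detectable trace in each
#: evidence type (probability an associated, fully-studied pair is elevated).
#: Gene fusion is rare in eukaryotes; gene neighborhood is weakly relevant
#: outside operon-bearing genomes; literature-derived sources are rich.
DEFAULT_INFORMATIVENESS = {
    "coexpression": 0.7,
    "phylogenetic": 0.6,
    "domain": 0.7,
    "cocitation": 0.9,
    "fusion": 0.1,
    "neighborhood": 0.3,
    "interolog_LC": 0.8,
    "interolog_Y2H": 0.6,
    "interolog_IP": 0.7,
}

#: Study-intensity coupling per evidence type.  Genome-scale measurements
#: (expression, phylogenetic profiles) are only mildly biased toward
#: well-studied proteins; literature-derived evidence is strongly biased.
DEFAULT_COVERAGE_BIAS = {
    "coexpression": 0.75,
    "phylogenetic": 0.75,
    "domain": 1.3,
    "cocitation": 1.75,
    "fusion": 1.0,
    "neighborhood": 1.0,
    "interolog_LC": 1.5,
    "interolog_Y2H": 1.25,
    "interolog_IP": 1.5,
}

_METHOD_POOL = (
    "two hybrid",
    "coimmunoprecipitation",
    "tandem affinity purification",
    "x-ray crystallography",
    "cosedimentation",
)


@dataclass(frozen=True)
class WorldConfig:
    """Parameters of the synthetic world.

    The defaults describe the standard study conditions used throughout
    the package's experiments: 300 proteins, 50 fractions, 50 disjoint
    complexes of 3-5 members each embedded in a functional module with 2
    associated non-complex proteins, informative and coverage-biased
    external features, and a 2010-2018 interaction catalog whose
    discoveries before the 2017 time-split are biased toward well-studied
    proteins while later discoveries are unbiased.
    """

    n_proteins: int = 300
    n_complexes: int = 50
    complex_size_range: tuple[int, int] = (3, 5)
    n_fractions: int = 50
    peak_width_range: tuple[float, float] = (1.5, 3.0)
    peak_jitter_sd: float = 0.3
    noise_sd: float = 0.12
    missing_rate: float = 0.2
    peaks_per_replicate: bool = True
    monomer_peaks: bool = False
    allow_overlap: bool = False
    # functional-association layer
    complexes_per_module: int = 1
    module_extra_proteins: int = 3
    known_complex_fraction: float = 0.6
    known_complex_bias: float = 2.0
    # external features; None selects the per-kind defaults below
    feature_informativeness: float | dict | None = None
    coverage_bias: float | dict | None = None
    base_coverage: float = 0.8
    binary_background_rate: float = 0.01
    spurious_association_rate: float = 0.02
    nonphysical_association_factor: float = 1.0
    undocumented_elevation_factor: float = 0.0
    # interaction catalog
    catalog_years: tuple[int, int] = (2010, 2018)
    detection_rate: float = 0.12
    detection_floor: float = 0.04
    bias_strength: float = 2.0
    post_cutoff_year: int | None = 2017
    post_cutoff_bias_strength: float = 0.0
    post_cutoff_detection_rate: float | None = 0.3
    catalog_fp_rate: float = 0.05
    species: str = "species_0"
    # annotations / publications
    annotation_coherence: float = 0.9
    publication_scale: float = 10.0
    seed: int = 0

    def __post_init__(self):
        probs = {
            "missing_rate": self.missing_rate,
            "known_complex_fraction": self.known_complex_fraction,
            "base_coverage": self.base_coverage,
            "binary_background_rate": self.binary_background_rate,
            "spurious_association_rate": self.spurious_association_rate,
            "undocumented_elevation_factor": self.undocumented_elevation_factor,
            "detection_rate": self.detection_rate,
            "detection_floor": self.detection_floor,
            "catalog_fp_rate": self.catalog_fp_rate,
            "annotation_coherence": self.annotation_coherence,
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be a probability, got {p}")
        for kind in FEATURE_KINDS:
            if not 0.0 <= self.informativeness_for(kind) <= 1.0:
                raise ValueError("feature_informativeness must be in [0, 1]")
            if not 0.0 <= self.coverage_bias_for(kind):
                raise ValueError("coverage_bias must be non-negative")
        if self.complex_size_range[0] < 2:
            raise ValueError("complexes need at least 2 members")
        if self.n_fractions < 5:
            raise ValueError("need at least 5 fractions")

    def informativeness_for(self, kind: str) -> float:
        if self.feature_informativeness is None:
            return DEFAULT_INFORMATIVENESS[kind]
        if isinstance(self.feature_informativeness, dict):
            return self.feature_informativeness.get(kind, 0.0)
        return self.feature_informativeness

    def coverage_bias_for(self, kind: str) -> float:
        if self.coverage_bias is None:
            return DEFAULT_COVERAGE_BIAS[kind]
        if isinstance(self.coverage_bias, dict):
            return self.coverage_bias.get(kind, 0.0)
        return self.coverage_bias

    def stream(self, name: str, *extra: int) -> np.random.Generator:
        return np.random.default_rng(
            [self.seed & 0x7FFFFFFF, _STREAMS[name], *extra]
        )


@dataclass
class SyntheticWorld:
    """Ground truth: complexes, modules, interactions, study intensity."""

    proteins: list[str]
    true_complexes: ComplexSet
    known_complexes: ComplexSet
    modules: dict[str, frozenset]
    true_interactions: set[tuple[str, str]]
    associated_pairs: set[tuple[str, str]]
    nonphysical_associations: set[tuple[str, str]]
    study_intensity: pd.Series
    peak_positions: dict[str, float]
    config: WorldConfig

    @property
    def complexed_proteins(self) -> set[str]:
        return self.true_complexes.proteins

    def complex_of(self, protein: str) -> str | None:
        for cid, members in self.true_complexes.complexes.items():
            if protein in members:
                return cid
        return None


def generate_world(config: WorldConfig) -> SyntheticWorld:
    """Draw a ground-truth world from the configuration.

    Complexes are disjoint by default (raises on infeasible configs);
    study intensity is log-normal with sigma = 1, reflecting heavy-tailed
    publication attention.
    """
    rng = config.stream("world")
    n = config.n_proteins
    width = len(str(n))
    proteins = [f"P{i + 1:0{width}d}" for i in range(n)]
    lo, hi = config.complex_size_range
    if not config.allow_overlap and config.n_complexes * hi > n:
        raise ValueError(
            f"{config.n_complexes} disjoint complexes of up to {hi} members "
            f"cannot fit in {n} proteins"
        )
    sizes = rng.integers(lo, hi + 1, size=config.n_complexes)
    order = list(rng.permutation(proteins))
    complexes: dict[str, frozenset] = {}
    cursor = 0
    for c, size in enumerate(sizes):
        cid = f"CPX{c + 1:03d}"
        if config.allow_overlap:
            members = rng.choice(proteins, size=size, replace=False)
        else:
            members = order[cursor : cursor + size]
            cursor += size
        complexes[cid] = frozenset(members)
    true_complexes = (
        ComplexSet(complexes) if complexes else ComplexSet({})
    )

    # functional modules: groups of complexes plus associated extras
    complexed = set().union(*complexes.values()) if complexes else set()
    free = [p for p in order if p not in complexed]
    modules: dict[str, frozenset] = {}
    cids = sorted(complexes)
    per = max(config.complexes_per_module, 1)
    cursor = 0
    for m in range(math.ceil(len(cids) / per) if cids else 0):
        group = cids[m * per : (m + 1) * per]
        members = set().union(*(complexes[c] for c in group))
        for _ in range(config.module_extra_proteins):
            if free:
                members.add(free.pop())
            else:  # extras exhausted: reuse an unrelated non-member protein
                pool = [p for p in proteins if p not in members]
                members.add(pool[int(rng.integers(len(pool)))])
        modules[f"MOD{m + 1:03d}"] = frozenset(members)

    def _pairs(groups) -> set[tuple[str, str]]:
        out: set[tuple[str, str]] = set()
        for members in groups:
            ms = sorted(members)
            for i in range(len(ms)):
                for j in range(i + 1, len(ms)):
                    out.add((ms[i], ms[j]))
        return out

    true_interactions = _pairs(complexes.values())
    associated = _pairs(modules.values()) | true_interactions

    intensity = pd.Series(
        rng.lognormal(mean=0.0, sigma=1.0, size=n), index=proteins,
        name="study_intensity",
    )

    # functional associations without physical interaction: cross-module
    # pairs (co-regulation, pathway co-membership, incidental co-citation)
    # that genomic evidence links but that never co-elute and are never
    # catalogued as interactions; sampling favors well-studied proteins
    n_nonphys = int(
        round(config.nonphysical_association_factor * len(true_interactions))
    )
    nonphysical: set[tuple[str, str]] = set()
    if n_nonphys:
        u = (intensity.rank(method="average") - 0.5) / n
        p_sel = (u**2 / (u**2).sum()).to_numpy()
        attempts = 0
        while len(nonphysical) < n_nonphys and attempts < 50 * n_nonphys:
            attempts += 1
            a, b = rng.choice(proteins, size=2, replace=False, p=p_sel)
            pair = (a, b) if a < b else (b, a)
            if pair not in associated:
                nonphysical.add(pair)
    associated |= nonphysical
    peaks = {
        cid: float(rng.uniform(3.0, config.n_fractions - 2.0)) for cid in cids
    }
    n_known = int(round(config.known_complex_fraction * len(cids)))
    if n_known and cids:
        # literature-curated reference complexes are themselves biased
        # toward well-studied proteins: sample complexes weighted by the
        # geometric mean of their members' study intensity
        gm = np.array(
            [
                float(np.exp(np.mean(np.log(intensity[list(complexes[c])]))))
                for c in cids
            ]
        )
        weights = gm**config.known_complex_bias
        known_ids = sorted(
            rng.choice(cids, size=n_known, replace=False, p=weights / weights.sum())
        )
    else:
        known_ids = []
    known = true_complexes.subset(known_ids) if known_ids else ComplexSet({})
    return SyntheticWorld(
        proteins=proteins,
        true_complexes=true_complexes,
        known_complexes=known,
        modules=modules,
        true_interactions=true_interactions,
        associated_pairs=associated,
        nonphysical_associations=nonphysical,
        study_intensity=intensity,
        peak_positions=peaks,
        config=config,
    )


def simulate_elution(
    world: SyntheticWorld, config: WorldConfig | None = None, replicate: int = 0
) -> ElutionMatrix:
    """Simulate one chromatogram matrix from the world.

    Complexed proteins elute as a Gaussian peak near their complex's
    position (small jitter); non-complexed proteins get independent random
    peak positions.  Peaks have unit amplitude before additive Gaussian
    noise; entries are set missing independently.  ``replicate`` selects
    an independent noise realization (a new experiment on the same
    world).
    """
    config = config or world.config
    rng = config.stream("elution", replicate)
    F = config.n_fractions
    x = np.arange(1, F + 1, dtype=float)
    protein_complex = {}
    for cid, members in world.true_complexes.complexes.items():
        for p in members:
            protein_complex.setdefault(p, cid)
    if config.peaks_per_replicate:
        # each experiment is its own separation gradient: complexes elute
        # at condition-specific positions, so different experiments resolve
        # (and confuse) different complexes
        positions = {
            cid: float(rng.uniform(3.0, F - 2.0))
            for cid in world.true_complexes.complexes
        }
    else:
        positions = world.peak_positions
    profiles = np.empty((len(world.proteins), F))
    for i, p in enumerate(world.proteins):
        cid = protein_complex.get(p)
        if cid is not None:
            center = positions[cid] + rng.normal(0.0, config.peak_jitter_sd)
        else:
            center = rng.uniform(1.0, F)
        sigma = rng.uniform(*config.peak_width_range)
        profile = np.exp(-((x - center) ** 2) / (2 * sigma**2))
        if config.monomer_peaks and cid is not None:
            mono_center = rng.uniform(1.0, F)
            mono_sigma = rng.uniform(*config.peak_width_range)
            profile = profile + 0.5 * np.exp(
                -((x - mono_center) ** 2) / (2 * mono_sigma**2)
            )
        profiles[i] = profile + rng.normal(0.0, config.noise_sd, size=F)
    if config.missing_rate > 0:
        mask = rng.random(profiles.shape) < config.missing_rate
        profiles[mask] = np.nan
    df = pd.DataFrame(profiles, index=world.proteins)
    return ElutionMatrix(df, condition=f"synthetic_rep{replicate}")


def _study_percentiles(world: SyntheticWorld) -> pd.Series:
    ranks = world.study_intensity.rank(method="average")
    return (ranks - 0.5) / len(ranks)


#: Evidence types that document a physical interaction only once it has
#: entered the literature: their elevation of a *true* pair is gated on
#: the pair's presence in the known-interaction catalog.
LITERATURE_KINDS = frozenset(
    {"cocitation", "domain", "interolog_LC", "interolog_Y2H", "interolog_IP"}
)


def simulate_genomic_feature(
    world: SyntheticWorld,
    kind: str,
    config: WorldConfig | None = None,
    known_pairs: set | None = None,
) -> pd.DataFrame:
    """Simulate one external genomic feature table over all protein pairs.

    Functionally associated (co-module or cross-module) pairs receive
    elevated scores with probability
    ``feature_informativeness * (u_a u_b)^coverage_bias`` -- evidence for
    an association only exists where someone looked, so with positive
    coverage bias elevation favors well-studied pairs, while at
    ``coverage_bias=0`` every associated pair is elevated with probability
    ``feature_informativeness`` exactly.  For literature-derived evidence
    types (co-citation, domain-domain interactions, interologs) a *true*
    interaction is additionally elevated only if it already appears in
    ``known_pairs`` (the pre-time-split catalog): the literature cannot
    document a physical interaction nobody has reported.  This gate is
    active only when ``known_pairs`` is given and the kind's coverage
    bias is positive.

    All other pairs draw from the background distribution.  A pair's
    score is *observed* with probability
    ``base_coverage * (u_a u_b)^coverage_bias`` where ``u`` is the
    protein's study-intensity percentile; with ``coverage_bias=0``
    coverage is independent of study intensity.  Binary kinds (domain,
    interologs) emit 0/1; correlation-like kinds emit values in [-1, 1],
    score-like kinds in [0, 1].
    """
    if kind not in FEATURE_KINDS:
        raise ValueError(f"unknown feature kind: {kind!r}")
    config = config or world.config
    rng = config.stream("feature", FEATURE_KINDS.index(kind))
    proteins = np.array(world.proteins, dtype=object)
    n = len(proteins)
    iu, ju = np.triu_indices(n, k=1)

    index = {p: i for i, p in enumerate(proteins)}

    def pair_mask(pairs) -> np.ndarray:
        m = np.zeros((n, n), dtype=bool)
        for a, b in pairs:
            m[index[a], index[b]] = True
            m[index[b], index[a]] = True
        return m[iu, ju]

    assoc = pair_mask(world.associated_pairs)

    u = _study_percentiles(world).to_numpy()
    bias = config.coverage_bias_for(kind)
    informativeness = config.informativeness_for(kind)
    # evidence for an association only exists where someone looked: the
    # elevation probability carries the same study-intensity coupling as
    # the observation mask (no coupling when coverage_bias = 0).  Pairs of
    # well-studied proteins additionally pick up spurious association
    # signals (e.g. incidental co-citation) at a low, equally-coupled rate.
    uu = u[iu] * u[ju]
    p_elev = np.where(
        assoc,
        informativeness * uu**bias,
        config.spurious_association_rate * informativeness * uu**bias,
    )
    if known_pairs is not None and bias > 0:
        undocumented_true = pair_mask(world.true_interactions - known_pairs)
        # the literature cannot document an unreported interaction at all;
        # genome-scale evidence still carries a (damped) signal for it
        factor = (
            0.0 if kind in LITERATURE_KINDS
            else config.undocumented_elevation_factor
        )
        p_elev = np.where(undocumented_true, factor * p_elev, p_elev)
    elevated = rng.random(len(iu)) < p_elev

    if kind in BINARY_KINDS:
        scores = (rng.random(len(iu)) < config.binary_background_rate).astype(float)
        scores[elevated] = 1.0
        # absence of binary evidence is itself an observation (a pair either
        # has a catalogued interolog / DDI or it does not), so indicator
        # columns are complete; the study bias lives in where the 1s are
        observed = np.ones(len(iu), dtype=bool)
    else:
        if kind in ("coexpression", "phylogenetic"):
            scores = rng.uniform(-0.6, 0.6, size=len(iu))
            scores[elevated] = rng.uniform(0.6, 1.0, size=int(elevated.sum()))
        else:
            # cocitation-like scores in [0, 1]: the background itself grows
            # with study intensity (well-studied pairs are co-mentioned at
            # base rates regardless of any true association)
            scores = rng.uniform(0.0, 0.4, size=len(iu)) * (
                (u[iu] * u[ju]) ** (bias / 2.0)
            )
            scores[elevated] = rng.uniform(0.55, 1.0, size=int(elevated.sum()))
        p_obs = config.base_coverage * (u[iu] * u[ju]) ** bias
        observed = rng.random(len(iu)) < p_obs

    table = pd.DataFrame(
        {"id_a": proteins[iu[observed]], "id_b": proteins[ju[observed]],
         "score": scores[observed]}
    )
    return sort_pair_table(table)


def simulate_interaction_catalog(
    world: SyntheticWorld, config: WorldConfig | None = None
) -> InteractionCatalog:
    """Simulate the year-stamped catalog of known interactions.

    Each true interaction is independently discovered in each catalog year
    with probability ``detection_rate * g^bias_strength`` (capped at 1),
    where ``g`` is the geometric mean of the pair's study intensities --
    discovery favors well-studied proteins.  Years at or past
    ``post_cutoff_year`` instead use ``post_cutoff_bias_strength`` and
    ``post_cutoff_detection_rate``, so the validation-era discovery
    process can be made independent of study intensity.  A discovered pair
    yields one record carrying all its discovery years, one synthetic
    publication id per year, a method string, and the species tag.  False
    positive records (non-interacting pairs) are added at
    ``catalog_fp_rate`` of the total record count.
    """
    config = config or world.config
    rng = config.stream("catalog")
    first, last = config.catalog_years
    years = np.arange(first, last + 1)
    if len(years) == 0:
        return InteractionCatalog([])
    intensity = world.study_intensity
    records: list[InteractionRecord] = []
    pub_counter = 0
    true_pairs = sorted(world.true_interactions)
    for a, b in true_pairs:
        g = math.sqrt(intensity[a] * intensity[b])
        hit_years = []
        for y in years:
            if config.post_cutoff_year is not None and y >= config.post_cutoff_year:
                rate = (
                    config.post_cutoff_detection_rate
                    if config.post_cutoff_detection_rate is not None
                    else config.detection_rate
                )
                exponent = config.post_cutoff_bias_strength
                floor = 0.0
            else:
                rate = config.detection_rate
                exponent = config.bias_strength
                floor = config.detection_floor
            p = min(1.0, floor + rate * g**exponent)
            if rng.random() < p:
                hit_years.append(int(y))
        if hit_years:
            pmids = []
            for y in hit_years:
                pub_counter += 1
                pmids.append(f"SPM{pub_counter:06d}")
            records.append(
                InteractionRecord(
                    id_a=a,
                    id_b=b,
                    method=str(rng.choice(_METHOD_POOL)),
                    pmids=tuple(pmids),
                    years=tuple(hit_years),
                    species=config.species,
                )
            )
    # false-positive records: catalogued pairs that are not true interactions
    if config.catalog_fp_rate > 0 and records:
        n_fp = int(round(
            config.catalog_fp_rate * len(records) / (1 - config.catalog_fp_rate)
        ))
        proteins = world.proteins
        true_set = world.true_interactions
        added = 0
        while added < n_fp:
            a, b = rng.choice(proteins, size=2, replace=False)
            if a > b:
                a, b = b, a
            if (a, b) in true_set:
                continue
            pub_counter += 1
            records.append(
                InteractionRecord(
                    id_a=a,
                    id_b=b,
                    method=str(rng.choice(_METHOD_POOL)),
                    pmids=(f"SPM{pub_counter:06d}",),
                    years=(int(rng.choice(years)),),
                    species=config.species,
                )
            )
            added += 1
    return InteractionCatalog(records)


def simulate_annotations(
    world: SyntheticWorld,
    n_terms: int | None = None,
    size_range: tuple[int, int] | None = None,
    coherence: float | None = None,
    config: WorldConfig | None = None,
) -> AnnotationTable:
    """Simulate GO-like annotations aligned with the functional modules.

    Each term is linked round-robin to a module; each module member is
    annotated with the term with probability ``coherence`` (1 annotates
    the whole module).  Terms beyond the module count, or all terms when
    the world has no modules, annotate random protein sets of a size drawn
    from ``size_range``.  Evidence codes are sampled with a realistic mix
    (mostly experimental; some IEA/NAS rows that downstream filtering
    removes).
    """
    config = config or world.config
    if coherence is None:
        coherence = config.annotation_coherence
    rng = config.stream("annotation")
    module_ids = sorted(world.modules)
    if n_terms is None:
        n_terms = len(module_ids)
    if size_range is None:
        size_range = (3, 8)
    if not 1 <= size_range[0] <= size_range[1] <= len(world.proteins):
        raise ValueError("size_range must lie within [1, n_proteins]")
    codes = np.array(["IDA", "IMP", "TAS", "IEA", "NAS"], dtype=object)
    code_p = np.array([0.45, 0.2, 0.15, 0.15, 0.05])
    rows = []
    for t in range(n_terms):
        term = f"TERM{t + 1:04d}"
        if module_ids:
            members = sorted(world.modules[module_ids[t % len(module_ids)]])
            annotated = [p for p in members if rng.random() < coherence]
        else:
            size = int(rng.integers(size_range[0], size_range[1] + 1))
            annotated = sorted(rng.choice(world.proteins, size=size, replace=False))
        for p in annotated:
            rows.append(
                {
                    "protein": p,
                    "term": term,
                    "evidence_code": str(rng.choice(codes, p=code_p)),
                }
            )
    return AnnotationTable(
        pd.DataFrame(rows, columns=["protein", "term", "evidence_code"])
    )


def simulate_publication_counts(
    world: SyntheticWorld, config: WorldConfig | None = None
) -> pd.Series:
    """Per-protein publication counts: Poisson with mean ~ study intensity."""
    config = config or world.config
    rng = config.stream("publications")
    means = config.publication_scale * world.study_intensity.to_numpy()
    counts = rng.poisson(means)
    return pd.Series(counts, index=world.proteins, name="publication_count")


def simulate_study_inputs(
    config: WorldConfig, n_datasets: int = 5
) -> dict:
    """Generate everything one sweep needs: world, observables, datasets.

    One world (one organism's complexes, features, catalog, annotations
    and publication record) is observed by ``n_datasets`` independent
    co-elution experiments.  Returns a dict with keys ``world``,
    ``matrices`` (dataset id -> ElutionMatrix), ``external`` (feature kind
    -> pair table), ``catalog``, ``annotations``, ``publication_counts``
    and ``complexes`` (the known reference subset used for training).
    """
    world = generate_world(config)
    matrices = {
        f"dataset_{d + 1}": simulate_elution(world, config, replicate=d)
        for d in range(n_datasets)
    }
    catalog = simulate_interaction_catalog(world, config)
    known = catalog.pairs_known_before(config.post_cutoff_year)
    external = {
        kind: simulate_genomic_feature(world, kind, config, known_pairs=known)
        for kind in FEATURE_KINDS
    }
    return {
        "world": world,
        "matrices": matrices,
        "external": external,
        "catalog": catalog,
        "annotations": simulate_annotations(world, config=config),
        "publication_counts": simulate_publication_counts(world, config),
        "complexes": world.known_complexes,
    }
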