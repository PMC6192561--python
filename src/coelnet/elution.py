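"""Dataset-derived pair features from co-elution chromatograms.

A co-elution (protein correlation profiling) experiment quantifies each
protein's abundance across an ordered series of chromatographic fractions.
Proteins participating in the same complex co-migrate, so their
chromatograms -- abundance-vs-fraction profiles -- are correlated.  This
module computes, for every co-quantified protein pair, the six profile
similarity features used by PrInCE-style classifiers:

========================  =====================================================
``euclidean_distance``    Euclidean distance between cleaned profiles.
``pearson_r``             Pearson correlation over jointly observed fractions.
``pearson_p``             Two-sided P-value of that correlation.
``cleaned_pearson``       Pearson correlation between cleaned profiles.
``coapex_distance``       |argmax(a) - argmax(b)| in fractions.
``gaussian_min_distance`` Minimum distance between fitted Gaussian components.
========================  =====================================================

Profile "cleaning" imputes isolated single missing values by the mean of
their neighbors and replaces remaining missing values with near-zero
Gaussian noise.  Deconvolution fits a mixture of one to five Gaussians by
bounded nonlinear least squares, selecting the component count by
corrected AIC.

Fractions are 1-based throughout.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "ElutionMatrix",
    "GaussianMixtureFit",
    "filter_proteins",
    "clean_profile",
    "euclidean_distance",
    "pearson_with_pvalue",
    "co_apex_distance",
    "fit_gaussian_mixture",
    "min_gaussian_distance",
    "build_pair_features",
    "sort_pair_table",
    "write_pair_features",
    "read_pair_features",
]

#: Missing-value noise scale as a fraction of the profile's observed maximum.
NOISE_FLOOR_FRACTION = 0.05

#: Maximum number of Gaussian components fitted per profile.
MAX_COMPONENTS = 5

FEATURE_COLUMNS = [
    "euclidean_distance",
    "pearson_r",
    "pearson_p",
    "cleaned_pearson",
    "coapex_distance",
    "gaussian_min_distance",
]


class ElutionMatrix:
    """A proteins x fractions abundance table with missing values.

    Parameters
    ----------
    data : pandas.DataFrame
        Rows indexed by unique protein identifiers, columns the ordered
        fractions (any labels; stored as ``fraction_1..fraction_F``).
        Missing quantifications are NaN.
    condition : str
        Free-text condition / replicate label.
    """

    def __init__(self, data: pd.DataFrame, condition: str = "default"):
        if data.index.has_duplicates:
            raise ValueError("protein identifiers must be unique")
        if data.shape[1] < 5:
            raise ValueError("an elution matrix needs at least 5 fractions")
        data = data.copy()
        data.columns = [f"fraction_{i}" for i in range(1, data.shape[1] + 1)]
        data.index.name = "protein"
        self.data = data.astype(float)
        self.condition = condition

    @property
    def proteins(self) -> list[str]:
        return list(self.data.index)

    @property
    def n_fractions(self) -> int:
        return self.data.shape[1]

    def profile(self, protein: str) -> np.ndarray:
        return self.data.loc[protein].to_numpy()

    def __len__(self) -> int:
        return len(self.data)

    # -- I/O ----------------------------------------------------------------

    def to_csv(self, path) -> None:
        """Write as CSV; empty cells encode missing values."""
        self.data.to_csv(path, na_rep="")

    @classmethod
    def from_csv(cls, path, condition: str = "default") -> "ElutionMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(df, condition=condition)


@dataclass
class GaussianMixtureFit:
    """Result of deconvolving one chromatogram into Gaussian components.

    ``components`` holds (amplitude, center, width) triples with amplitude
    >= 0 and width > 0; ``r_squared`` is the coefficient of determination of
    the selected model and ``aicc`` its corrected-AIC value.
    """

    components: list[tuple[float, float, float]]
    r_squared: float = float("nan")
    aicc: float = float("nan")
    fallback: bool = False

    @property
    def n_components(self) -> int:
        return len(self.components)

    def params(self) -> np.ndarray:
        """Component parameters as an (k, 3) array of (center, width, amplitude)."""
        return np.array([(mu, sigma, a) for a, mu, sigma in self.components])


# ---------------------------------------------------------------------------
# Filtering and cleaning


def _is_isoform(protein: str) -> bool:
    # accession-dash-number dialect, e.g. "P12345-2"
    head, dash, tail = protein.rpartition("-")
    return bool(dash) and tail.isdigit()


def filter_proteins(
    matrix: ElutionMatrix,
    min_fractions: int = 4,
    drop_isoforms: bool = False,
) -> ElutionMatrix:
    """Remove sparsely quantified proteins (and optionally isoforms).

    Proteins quantified in fewer than ``min_fractions`` fractions (default:
    three or fewer) are dropped, as are identifiers with an isoform suffix
    when ``drop_isoforms`` is set.
    """
    observed = matrix.data.notna().sum(axis=1)
    keep = observed >= min_fractions
    if drop_isoforms:
        keep &= ~matrix.data.index.map(_is_isoform)
    out = matrix.data.loc[keep]
    if out.empty:
        warnings.warn("no proteins survive filtering", stacklevel=2)
    return ElutionMatrix(out, condition=matrix.condition)


def clean_profile(
    a: np.ndarray,
    rng: np.random.Generator,
    noise_floor: float | None = None,
) -> np.ndarray:
    """Impute missing values in one chromatogram.

    Isolated single missing values (both neighbors observed) become the
    mean of the two flanking values; all remaining missing values are
    replaced by independent draws from a zero-mean Gaussian whose standard
    deviation is ``noise_floor`` (default: 5% of the observed maximum).
    Observed values are never altered.
    """
    a = np.asarray(a, dtype=float)
    out = a.copy()
    missing = np.isnan(a)
    if missing.all():
        warnings.warn("all-missing profile: output is pure noise", stacklevel=2)
        sd = noise_floor if noise_floor is not None else 0.0
        return rng.normal(0.0, sd, size=a.shape) if sd > 0 else np.zeros_like(a)
    if noise_floor is None:
        noise_floor = NOISE_FLOOR_FRACTION * np.nanmax(a)
    # isolated single gaps first
    for i in np.flatnonzero(missing):
        if 0 < i < len(a) - 1 and not np.isnan(a[i - 1]) and not np.isnan(a[i + 1]):
            out[i] = 0.5 * (a[i - 1] + a[i + 1])
    still = np.isnan(out)
    n = int(still.sum())
    if n:
        noise = rng.normal(0.0, noise_floor, size=n) if noise_floor > 0 else np.zeros(n)
        out[still] = noise
    return out


# ---------------------------------------------------------------------------
# Pairwise profile features


def euclidean_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Euclidean distance ``sqrt(sum_f (a_f - b_f)^2)`` between cleaned profiles."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape:
        raise ValueError("profiles must have equal length")
    return float(np.sqrt(np.sum((a - b) ** 2)))


def pearson_with_pvalue(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Pearson correlation over jointly observed fractions, with P-value.

    The correlation is computed on the fractions where both profiles are
    observed; the two-sided P-value uses the t transform
    ``t = r * sqrt((n - 2) / (1 - r^2))`` with ``n - 2`` degrees of freedom.
    Returns ``(nan, nan)`` with fewer than 3 co-observed fractions or zero
    variance in either profile.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    joint = ~np.isnan(a) & ~np.isnan(b)
    n = int(joint.sum())
    if n < 3:
        return float("nan"), float("nan")
    x, y = a[joint], b[joint]
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        return float("nan"), float("nan")
    r = float(np.clip(np.corrcoef(x, y)[0, 1], -1.0, 1.0))
    if abs(r) == 1.0:
        p = np.finfo(float).tiny
    else:
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
        p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
        p = max(p, np.finfo(float).tiny)
    return r, min(p, 1.0)


def co_apex_distance(a: np.ndarray, b: np.ndarray) -> int:
    """Distance in fractions between the two profiles' maxima.

    Ties are broken by the earliest maximal fraction (``argmax`` on the
    cleaned profile).
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    return int(abs(int(np.argmax(a)) - int(np.argmax(b))))


# ---------------------------------------------------------------------------
# Gaussian mixture deconvolution


def _mixture(x: np.ndarray, *params: float) -> np.ndarray:
    y = np.zeros_like(x, dtype=float)
    for i in range(0, len(params), 3):
        a, mu, sigma = params[i : i + 3]
        y = y + a * np.exp(-((x - mu) ** 2) / (2.0 * sigma**2))
    return y


def _mixture_jac(x: np.ndarray, *params: float) -> np.ndarray:
    jac = np.empty((len(x), len(params)))
    for i in range(0, len(params), 3):
        a, mu, sigma = params[i : i + 3]
        z = (x - mu) / sigma
        g = np.exp(-0.5 * z * z)
        jac[:, i] = g
        jac[:, i + 1] = a * g * z / sigma
        jac[:, i + 2] = a * g * z * z / sigma
    return jac


def fit_gaussian_mixture(a: np.ndarray, max_components: int = MAX_COMPONENTS) -> GaussianMixtureFit:
    """Deconvolve one cleaned chromatogram into 1-5 Gaussians.

    Fits ``sum_i A_i exp(-(x - mu_i)^2 / (2 sigma_i^2))`` for k = 1..5 by
    bounded nonlinear least squares and returns the fit minimizing the
    corrected AIC.  Initialization is deterministic: the first component
    starts at the global apex, each further component at the largest
    absolute residual of the previous fit.  Bounds: ``mu`` in
    ``[-1, F + 2]``, ``sigma`` in ``[0.5, F]``, ``A`` in ``[0, 2 max]``.

    A degenerate profile (non-positive everywhere, or total fit failure)
    yields a single-component fallback at the apex with a warning.
    """
    y = np.asarray(a, dtype=float)
    F = len(y)
    x = np.arange(1, F + 1, dtype=float)
    ymax = float(np.max(y))
    if not np.isfinite(ymax) or ymax <= 0:
        warnings.warn("degenerate profile: single-component fallback", stacklevel=2)
        return GaussianMixtureFit(
            components=[(max(ymax, 0.0), float(np.argmax(y) + 1), 1.0)], fallback=True
        )

    lo = (0.0, -1.0, 0.5)
    hi = (2.0 * ymax, F + 2.0, float(F))
    best: GaussianMixtureFit | None = None
    prev_params: list[float] = []
    prev_resid = y.copy()
    for k in range(1, max_components + 1):
        n_par = 3 * k
        if F - n_par - 2 <= 0:  # AICc undefined; model too rich for the grid
            break
        apex = int(np.argmax(np.abs(prev_resid)))
        init = prev_params + [max(float(np.abs(prev_resid[apex])), 1e-3), x[apex], 2.0]
        init = [float(np.clip(v, l, h)) for v, l, h in zip(init, lo * k, hi * k)]
        try:
            popt, _ = optimize.curve_fit(
                _mixture,
                x,
                y,
                p0=init,
                bounds=(lo * k, hi * k),
                jac=_mixture_jac,
                ftol=1e-8,
                xtol=1e-8,
                maxfev=100 * n_par,
            )
        except (RuntimeError, ValueError):
            continue
        resid = y - _mixture(x, *popt)
        rss = float(np.sum(resid**2))
        tss0 = float(np.sum((y - y.mean()) ** 2))
        # floor the RSS at numerical precision relative to the signal so a
        # noiseless profile cannot reward spurious extra components
        rss = max(rss, 1e-12 * tss0, 1e-300)
        aicc = (
            F * np.log(rss / F)
            + 2 * n_par
            + 2 * n_par * (n_par + 1) / (F - n_par - 1)
        )
        tss = float(np.sum((y - y.mean()) ** 2))
        r2 = 1.0 - rss / tss if tss > 0 else 0.0
        fit = GaussianMixtureFit(
            components=[tuple(popt[i : i + 3]) for i in range(0, n_par, 3)],
            r_squared=r2,
            aicc=aicc,
        )
        if best is None or aicc < best.aicc:
            best = fit
            worse_streak = 0
        else:
            worse_streak += 1
            if worse_streak >= 2:  # AICc rising; further components won't win
                break
        prev_params = list(popt)
        prev_resid = resid
    if best is None:
        warnings.warn("all mixture fits failed: single-component fallback", stacklevel=2)
        return GaussianMixtureFit(
            components=[(ymax, float(np.argmax(y) + 1), 1.0)], fallback=True
        )
    return best


def min_gaussian_distance(fa: GaussianMixtureFit, fb: GaussianMixtureFit) -> float:
    """Minimum Euclidean distance between any two components of two fits.

    Each component is represented by its (center, width, amplitude)
    parameter vector; the distance is the plain Euclidean distance between
    those vectors, minimized over all component pairs.
    """
    pa, pb = fa.params(), fb.params()
    if pa.size == 0 or pb.size == 0:
        raise ValueError("both fits must contain at least one component")
    diff = pa[:, None, :] - pb[None, :, :]
    return float(np.sqrt((diff**2).sum(axis=2)).min())


# ---------------------------------------------------------------------------
# The pair feature table


def _protein_rng(seed: int, protein: str) -> np.random.Generator:
    # keyed on the identifier, not the row position, so that reordering
    # proteins cannot change any profile's imputation noise
    return np.random.default_rng([seed & 0x7FFFFFFF, zlib.crc32(protein.encode())])


def _pairwise_raw_pearson(
    raw: np.ndarray, observed: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pairwise Pearson r / P over jointly observed fractions, vectorized."""
    n = raw.shape[0]
    r = np.full((n, n), np.nan)
    p = np.full((n, n), np.nan)
    counts = (observed.astype(np.int32) @ observed.T.astype(np.int32)).astype(float)
    filled = np.where(observed, raw, 0.0)
    for i in range(n):
        m = observed[i] & observed  # (n, F) joint masks against protein i
        nj = m.sum(axis=1).astype(float)
        ok = nj >= 3
        if not ok.any():
            continue
        xi = np.where(m, raw[i], 0.0)
        yj = np.where(m, filled, 0.0)
        sx = xi.sum(axis=1)
        sy = yj.sum(axis=1)
        sxx = (xi * xi).sum(axis=1)
        syy = (yj * yj).sum(axis=1)
        sxy = (xi * yj).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            cov = sxy - sx * sy / nj
            vx = sxx - sx * sx / nj
            vy = syy - sy * sy / nj
            ri = cov / np.sqrt(vx * vy)
        ri = np.where(ok & (vx > 1e-300) & (vy > 1e-300), ri, np.nan)
        ri = np.clip(ri, -1.0, 1.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            t = ri * np.sqrt((nj - 2) / (1.0 - ri * ri))
        pi = 2.0 * stats.t.sf(np.abs(t), df=np.maximum(nj - 2, 1))
        pi = np.where(np.abs(ri) >= 1.0, np.finfo(float).tiny, pi)
        pi = np.clip(pi, np.finfo(float).tiny, 1.0)
        r[i] = ri
        p[i] = np.where(np.isnan(ri), np.nan, pi)
    return r, p, counts


def build_pair_features(
    matrix: ElutionMatrix,
    seed: int = 0,
    min_joint_fractions: int = 3,
    fit_gaussians: bool = True,
) -> pd.DataFrame:
    """Compute the six dataset-derived features for every co-quantified pair.

    Returns a DataFrame with columns ``id_a``, ``id_b`` (sorted
    lexicographically within and across rows) followed by the six feature
    columns.  One row is emitted per unordered pair with at least
    ``min_joint_fractions`` jointly observed fractions; features that are
    undefined for a pair are NaN.  Deterministic for a fixed seed and
    invariant, up to row order, to protein reordering.
    """
    proteins = matrix.proteins
    n = len(proteins)
    if n < 2:
        return pd.DataFrame(columns=["id_a", "id_b", *FEATURE_COLUMNS])
    raw = matrix.data.to_numpy()
    observed = ~np.isnan(raw)

    cleaned = np.vstack(
        [clean_profile(raw[i], _protein_rng(seed, proteins[i])) for i in range(n)]
    )

    D = squareform(pdist(cleaned, metric="euclidean"))
    with np.errstate(invalid="ignore", divide="ignore"):
        r_clean = np.corrcoef(cleaned)
    apex = np.argmax(cleaned, axis=1)
    coapex = np.abs(apex[:, None] - apex[None, :]).astype(float)
    r_raw, p_raw, joint = _pairwise_raw_pearson(raw, observed)

    if fit_gaussians:
        # pad each protein's components to a fixed-width array; NaN padding
        # drops out of the nanmin below
        params = np.full((n, MAX_COMPONENTS, 3), np.nan)
        for i in range(n):
            if observed[i].sum() >= 5:
                fit = fit_gaussian_mixture(cleaned[i])
                params[i, : fit.n_components] = fit.params()
        dg = np.full((n, n), np.inf)
        for a in range(MAX_COMPONENTS):
            for b in range(MAX_COMPONENTS):
                diff = params[:, None, a, :] - params[None, :, b, :]
                d = np.sqrt((diff**2).sum(axis=2))
                dg = np.fmin(dg, np.where(np.isnan(d), np.inf, d))
        dg[~np.isfinite(dg)] = np.nan
    else:
        dg = np.full((n, n), np.nan)

    iu, ju = np.triu_indices(n, k=1)
    keep = joint[iu, ju] >= min_joint_fractions
    iu, ju = iu[keep], ju[keep]
    ids = np.array(proteins, dtype=object)
    a_ids, b_ids = ids[iu], ids[ju]
    swap = a_ids > b_ids
    a_ids[swap], b_ids[swap] = b_ids[swap], a_ids[swap]
    table = pd.DataFrame(
        {
            "id_a": a_ids,
            "id_b": b_ids,
            "euclidean_distance": D[iu, ju],
            "pearson_r": r_raw[iu, ju],
            "pearson_p": p_raw[iu, ju],
            "cleaned_pearson": r_clean[iu, ju],
            "coapex_distance": coapex[iu, ju],
            "gaussian_min_distance": dg[iu, ju],
        }
    )
    return sort_pair_table(table)


def sort_pair_table(table: pd.DataFrame) -> pd.DataFrame:
    """Normalize a pair table: ids sorted within a row, rows sorted lexicographically."""
    table = table.copy()
    a = table["id_a"].astype(str).to_numpy()
    b = table["id_b"].astype(str).to_numpy()
    swap = a > b
    a[swap], b[swap] = b[swap], a[swap]
    table["id_a"], table["id_b"] = a, b
    return table.sort_values(["id_a", "id_b"], kind="mergesort").reset_index(drop=True)


def write_pair_features(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False, na_rep="")


def read_pair_features(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
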