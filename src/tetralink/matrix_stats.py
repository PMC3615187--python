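"""Distance-matrix inference: Mantel tests, AICc ranking, PCO, screens.

All pairwise structure flows through :class:`skbio.DistanceMatrix`
(symmetric, hollow, labelled).  The lower triangle excluding the diagonal
— the condensed form, n(n-1)/2 entries — defines the unfolding used by
every statistic here.

The Mantel statistic correlates the condensed entries of two matrices and
tests it by jointly permuting the rows and columns of the second matrix
(the standard Mantel null), two-sided on |r| with the add-one permutation
p estimator.  Both the product-moment and the rank (Spearman) form are
available; the rank form is what the reproduced study's printed
coefficients reflect (see docs/methods.md).

Model ranking fits, for each candidate predictor matrix, an ordinary
least-squares regression of the unfolded response on the unfolded
predictor and scores it with the small-sample Akaike criterion

    AICc = m ln(RSS/m) + 2k + 2k(k+1)/(m-k-1),   k = 3,

treating the m = n(n-1)/2 pairs as the sample.  Candidates are ranked by
AICc; dAICc < 2 is strong support, dAICc > 10 or a Mantel p > 0.05 is
essentially none.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import pearsonr, rankdata
from skbio import DistanceMatrix

from .errors import (
    AlignmentError,
    ConfigurationError,
    InsufficientDataError,
    ValidationError,
)
from .lipids import SPECIES_CODES, LipidProfile

__all__ = [
    "DistanceMatrix",
    "MantelResult",
    "ModelRanking",
    "PCOResult",
    "profile_distance",
    "mantel",
    "aicc_of_model",
    "rank_models",
    "pco",
    "pearson_screen",
]


def profile_distance(profiles: Sequence[LipidProfile]) -> DistanceMatrix:
    """Euclidean distance between lipid profiles.

    Distances are computed over the raw (un-normalized) percent abundances
    of the 14 canonical species, matching how the published dissimilarity
    matrices were built.  All profiles must share one fraction.
    """
    if len(profiles) < 2:
        raise ValidationError("need at least two profiles")
    fractions = {p.fraction for p in profiles}
    if len(fractions) != 1:
        raise ValidationError(f"mixed fractions {sorted(fractions)}")
    ids = [p.spring_id for p in profiles]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValidationError(f"duplicate spring id(s) {dupes}")
    X = np.array([p.abundance_vector() for p in profiles], dtype=float)
    assert X.shape[1] == len(SPECIES_CODES)
    return DistanceMatrix(squareform(pdist(X)), ids=ids)


def _aligned_condensed(
    da: DistanceMatrix, db: DistanceMatrix
) -> tuple[np.ndarray, np.ndarray]:
    if set(da.ids) != set(db.ids):
        raise AlignmentError(
            f"label mismatch: {sorted(set(da.ids) ^ set(db.ids))}"
        )
    if tuple(da.ids) != tuple(db.ids):
        db = db.filter(da.ids)
    return da.condensed_form(), db.condensed_form()


@dataclass(frozen=True)
class MantelResult:
    """Outcome of one Mantel permutation test."""

    r: float
    p: float | None
    n_perm: int
    seed: int | None
    method: str = "pearson"

    @property
    def r2(self) -> float:
        return self.r * self.r


def mantel(
    da: DistanceMatrix,
    db: DistanceMatrix,
    n_perm: int = 999,
    seed: int | None = 0,
    method: str = "pearson",
) -> MantelResult:
    """Mantel correlation between two labelled distance matrices.

    ``r`` is the (product-moment or rank) correlation of the condensed
    entries and is deterministic; ``p`` is the two-sided add-one
    permutation estimate, reproducible given ``seed``.  ``n_perm = 0``
    yields ``p = None``.
    """
    if method not in ("pearson", "spearman"):
        raise ConfigurationError(f"unknown Mantel method {method!r}")
    if n_perm < 0:
        raise ConfigurationError("n_perm must be >= 0")
    va, vb = _aligned_condensed(da, db)
    if method == "spearman":
        # Ranks commute with joint row/column relabelling (the multiset of
        # entries is permutation-invariant), so rank once and permute ranks.
        va, vb = rankdata(va), rankdata(vb)
    if va.std() == 0 or vb.std() == 0:
        raise ValidationError("constant distance matrix; Mantel r undefined")

    def _corr(x: np.ndarray, y: np.ndarray) -> float:
        return float(np.corrcoef(x, y)[0, 1])

    r_obs = _corr(va, vb)
    if n_perm == 0:
        return MantelResult(r=r_obs, p=None, n_perm=0, seed=seed, method=method)

    n = len(da.ids)
    B = squareform(vb)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        r_perm = _corr(va, squareform(B[np.ix_(perm, perm)], checks=False))
        if abs(r_perm) >= abs(r_obs) - 1e-12:
            exceed += 1
    p = (1 + exceed) / (1 + n_perm)
    return MantelResult(r=r_obs, p=p, n_perm=n_perm, seed=seed, method=method)


_AICC_K = 3  # intercept, slope, error variance


def aicc_of_model(
    response: DistanceMatrix, predictor: DistanceMatrix
) -> float:
    """Small-sample AIC of the OLS fit response ~ predictor on unfolded pairs.

    A perfect fit (RSS ~ 0) is reported as ``-inf`` with a warning rather
    than an error, so a self-comparison sorts first without poisoning a
    ranking.
    """
    y, x = _aligned_condensed(response, predictor)
    m = len(y)
    if m <= _AICC_K + 1:
        raise InsufficientDataError(
            f"{m} pairs is too few for k={_AICC_K} parameters"
        )
    X = np.column_stack([np.ones(m), x])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    rss = float(np.sum((y - X @ beta) ** 2))
    if rss <= 1e-12 * max(1.0, float(np.sum(y**2))):
        warnings.warn(
            "residual sum of squares is ~0; AICc reported as -inf",
            RuntimeWarning,
            stacklevel=2,
        )
        return float("-inf")
    k = _AICC_K
    return m * np.log(rss / m) + 2 * k + 2 * k * (k + 1) / (m - k - 1)


@dataclass(frozen=True)
class ModelRanking:
    """AICc-ordered comparison of single-predictor distance models.

    ``table`` has one row per predictor with columns ``predictor, aicc,
    delta_aicc, mantel_r, mantel_r2, p, support``, sorted by ascending
    AICc (ties broken by predictor name for determinism).
    """

    table: pd.DataFrame
    n_perm: int
    seed: int | None
    method: str = "pearson"

    @property
    def best(self) -> str:
        return str(self.table.iloc[0]["predictor"])


def _support(delta: float, p: float | None) -> str:
    if delta > 10 or (p is not None and p > 0.05):
        return "none"
    if delta < 2:
        return "strong"
    return "intermediate"


def _predictor_seed(seed: int | None, name: str) -> int | None:
    # Order-invariant per-predictor stream: p-values must not depend on the
    # order in which predictors are supplied.
    if seed is None:
        return None
    return (seed * 2654435761 + zlib.crc32(name.encode())) % (2**31)


def rank_models(
    response: DistanceMatrix,
    predictors: Mapping[str, DistanceMatrix],
    n_perm: int = 999,
    seed: int | None = 0,
    method: str = "pearson",
) -> ModelRanking:
    """Rank candidate predictor matrices against one response matrix.

    Each predictor gets an AICc (OLS on unfolded pairs), dAICc relative to
    the best model, a Mantel r/r² and permutation p, and a support
    category.  The ranking is invariant to predictor input order and to
    the seed (which affects p-values only).
    """
    if not predictors:
        raise ConfigurationError("at least one predictor is required")
    rows = []
    for name, dm in predictors.items():
        res = mantel(
            response, dm, n_perm=n_perm,
            seed=_predictor_seed(seed, name), method=method,
        )
        rows.append(
            {
                "predictor": name,
                "aicc": aicc_of_model(response, dm),
                "mantel_r": res.r,
                "mantel_r2": res.r2,
                "p": res.p,
            }
        )
    table = (
        pd.DataFrame(rows)
        .sort_values(["aicc", "predictor"], kind="mergesort")
        .reset_index(drop=True)
    )
    table["delta_aicc"] = table["aicc"] - table["aicc"].iloc[0]
    table["support"] = [
        _support(d, p) for d, p in zip(table["delta_aicc"], table["p"])
    ]
    table = table[
        ["predictor", "aicc", "delta_aicc", "mantel_r", "mantel_r2", "p", "support"]
    ]
    return ModelRanking(table=table, n_perm=n_perm, seed=seed, method=method)


@dataclass(frozen=True)
class PCOResult:
    """Principal-coordinates embedding of a distance matrix.

    ``coordinates`` is a site x axis DataFrame for the positive-eigenvalue
    axes (each eigenvector scaled by the square root of its eigenvalue);
    ``eigenvalues`` holds the full spectrum in descending order, negative
    values included (reported, never corrected); ``pct_variance`` is per
    positive axis, as percent of the positive-eigenvalue sum.
    """

    coordinates: pd.DataFrame
    eigenvalues: np.ndarray
    pct_variance: np.ndarray


def pco(d: DistanceMatrix, n_axes: int | None = None) -> PCOResult:
    """Classical (metric) principal-coordinates analysis.

    Gower-centres -d²/2, eigendecomposes, and keeps the positive axes.
    Each axis is oriented so that its largest-magnitude coordinate is
    positive, making output reproducible across eigensolvers.
    """
    n = len(d.ids)
    if n < 3:
        raise ValidationError("PCO needs at least three sites")
    D2 = np.asarray(d.data, dtype=float) ** 2
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ D2 @ J
    eigval, eigvec = np.linalg.eigh((B + B.T) / 2)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]

    tol = 1e-8 * max(1.0, float(abs(eigval).max()))
    pos = eigval > tol
    n_pos = int(pos.sum())
    if n_pos == 0:
        warnings.warn(
            "no positive eigenvalues; degenerate (all-zero?) distances",
            RuntimeWarning,
            stacklevel=2,
        )
        coords = np.zeros((n, 0))
        pct = np.zeros(0)
    else:
        if n_axes is not None and n_axes > n_pos:
            warnings.warn(
                f"requested {n_axes} axes but only {n_pos} positive "
                "eigenvalues; truncating",
                RuntimeWarning,
                stacklevel=2,
            )
        keep = n_pos if n_axes is None else min(n_axes, n_pos)
        coords = eigvec[:, :keep] * np.sqrt(eigval[:keep])
        # Deterministic sign convention.
        for j in range(coords.shape[1]):
            i = int(np.argmax(np.abs(coords[:, j])))
            if coords[i, j] < 0:
                coords[:, j] = -coords[:, j]
        pct = eigval[:keep] / eigval[:n_pos].sum() * 100.0
    frame = pd.DataFrame(
        coords,
        index=pd.Index(list(d.ids), name="site"),
        columns=[f"PCO{j + 1}" for j in range(coords.shape[1])],
    )
    return PCOResult(coordinates=frame, eigenvalues=eigval, pct_variance=pct)


def pearson_screen(
    x: pd.DataFrame,
    y: pd.DataFrame,
    adjust: bool = False,
) -> pd.DataFrame:
    """All-pairs Pearson correlation screen between two column sets.

    Observations are aligned on the shared index (spring/site ids); each
    pair drops rows with a missing value in either column (pairwise
    deletion) and is skipped with a warning if fewer than three complete
    observations remain.  Two-sided p-values come from the t distribution
    with n-2 degrees of freedom; ``adjust`` adds a Benjamini-Hochberg
    ``q`` column.
    """
    shared = x.index.intersection(y.index)
    xs, ys = x.loc[shared], y.loc[shared]
    rows = []
    for xc in xs.columns:
        for yc in ys.columns:
            pair = pd.concat([xs[xc], ys[yc]], axis=1, keys=["x", "y"]).dropna()
            n = len(pair)
            if n < 3:
                warnings.warn(
                    f"pair ({xc!r}, {yc!r}) has only {n} complete "
                    "observations; skipped",
                    RuntimeWarning,
                    stacklevel=2,
                )
                continue
            r, p = pearsonr(pair["x"], pair["y"])
            rows.append({"x": xc, "y": yc, "r": float(r), "p": float(p), "n": n})
    out = pd.DataFrame(rows, columns=["x", "y", "r", "p", "n"])
    if adjust and not out.empty:
        from statsmodels.stats.multitest import multipletests

        out["q"] = multipletests(out["p"], method="fdr_bh")[1]
    return out
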