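"""Population substructure: classical MDS, Mantel tests, origin contingency tests.

Classical (metric) MDS, also known as principal coordinates analysis,
double-centers the squared distance matrix, eigendecomposes it and uses the
leading eigenvectors (scaled by the square roots of their eigenvalues) as
coordinates.  Axes with negative eigenvalues — present whenever the matrix
is not Euclidean-realizable — are reported but never used as coordinates.

The Mantel statistic is the Pearson correlation of the off-diagonal
upper-triangle entries of two distance matrices over the same labels; its
null distribution comes from simultaneous row/column permutations of the
second matrix.  The reported p is two-sided (|r_perm| >= |r_obs|) with
+1 smoothing.  Note the statistic is the *signed* correlation r, not an
R-squared, even though some reports print it under that name.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .diversity import DistanceMatrix
from .errors import DegenerateInputError, MetadataError

__all__ = [
    "MDSResult",
    "MantelResult",
    "classical_mds",
    "mantel",
    "origin_association_tests",
    "chi2_independence",
]


@dataclass
class MDSResult:
    labels: list[str]
    coordinates: np.ndarray        # (n, k), column means zero
    eigenvalues: np.ndarray        # all n, sorted descending (may be negative)
    proportion: np.ndarray         # variance fraction per retained axis

    def to_frame(self) -> pd.DataFrame:
        cols = [f"axis{i+1}" for i in range(self.coordinates.shape[1])]
        return pd.DataFrame(self.coordinates, index=self.labels, columns=cols)


def classical_mds(dm: DistanceMatrix, k: int = 2) -> MDSResult:
    """Classical MDS (principal coordinates) of a distance matrix.

    Requests ``k`` axes; axes whose eigenvalue is not positive are dropped,
    so fewer than ``k`` columns may come back (degenerate geometries).
    """
    n = dm.n
    if k >= n:
        raise DegenerateInputError(f"k={k} must be < number of points {n}")
    D2 = np.nan_to_num(dm.values, nan=0.0) ** 2
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ D2 @ J
    B = (B + B.T) / 2.0
    vals, vecs = np.linalg.eigh(B)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    pos = vals[:k] > 1e-10
    coords = vecs[:, :k][:, pos] * np.sqrt(vals[:k][pos])
    coords = coords - coords.mean(axis=0)  # numerically exact centering
    pos_sum = vals[vals > 0].sum()
    proportion = (vals[:k][pos] / pos_sum) if pos_sum > 0 else np.zeros(pos.sum())
    return MDSResult(list(dm.labels), coords, vals, proportion)


@dataclass
class MantelResult:
    r: float
    p: float
    n_perm: int
    seed: int | None


def _offdiag(values: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(values.shape[0], k=1)
    return values[iu]


def mantel(dm1: DistanceMatrix, dm2: DistanceMatrix, n_perm: int = 10_000,
           seed: int | None = None, exact: bool = False) -> MantelResult:
    """Mantel correlation between two distance matrices over the same labels.

    With ``exact=True`` the null is enumerated over all ``n!`` simultaneous
    row/column permutations (identity included, no smoothing) — feasible for
    small matrices and used to validate the Monte-Carlo path.
    """
    if dm1.labels != dm2.labels:
        raise MetadataError("Mantel requires identical labels in identical order")
    n = dm1.n
    if n < 3:
        raise DegenerateInputError("Mantel needs at least 3 labels")
    x = _offdiag(dm1.values)
    y = _offdiag(dm2.values)
    if np.std(x) == 0 or np.std(y) == 0:
        raise DegenerateInputError("constant distance matrix")
    r_obs = float(np.corrcoef(x, y)[0, 1])

    def r_of(perm: np.ndarray) -> float:
        y_perm = _offdiag(dm2.values[np.ix_(perm, perm)])
        return float(np.corrcoef(x, y_perm)[0, 1])

    if exact:
        import itertools

        rs = [r_of(np.asarray(p)) for p in itertools.permutations(range(n))]
        p = sum(abs(r) >= abs(r_obs) - 1e-12 for r in rs) / len(rs)
        return MantelResult(r_obs, p, len(rs), seed)

    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        if abs(r_of(rng.permutation(n))) >= abs(r_obs) - 1e-12:
            count += 1
    p = (count + 1) / (n_perm + 1)
    return MantelResult(r_obs, p, n_perm, seed)


@dataclass
class Chi2Result:
    chi2: float
    df: int
    p: float
    expected: np.ndarray
    low_expected: bool             # some expected cell < 5
    exact_p: float | None = None   # Fisher p for flagged 2x2 tables
    dropped: list[str] | None = None


def chi2_independence(counts: pd.DataFrame, correction: bool = False) -> Chi2Result:
    """Pearson chi-square test of independence on a contingency table.

    Zero-margin rows/columns are dropped (recorded in ``dropped``); when an
    expected cell is below 5 the result is flagged and, for 2x2 tables, a
    Fisher exact p is attached.
    """
    tab = counts.copy()
    dropped = []
    zero_rows = tab.index[(tab.sum(axis=1) == 0)]
    zero_cols = tab.columns[(tab.sum(axis=0) == 0)]
    if len(zero_rows) or len(zero_cols):
        dropped = [str(r) for r in zero_rows] + [str(c) for c in zero_cols]
        tab = tab.drop(index=zero_rows, columns=zero_cols)
    if tab.shape[0] < 2 or tab.shape[1] < 2:
        raise DegenerateInputError("contingency table needs >=2 rows and columns")
    chi2, p, df, expected = stats.chi2_contingency(tab.to_numpy(), correction=correction)
    low = bool((expected < 5).any())
    exact_p = None
    if low and tab.shape == (2, 2):
        exact_p = float(stats.fisher_exact(tab.to_numpy())[1])
    return Chi2Result(float(chi2), int(df), float(p), expected, low, exact_p,
                      dropped or None)


def origin_association_tests(counts: pd.DataFrame,
                             paired: pd.DataFrame | None = None,
                             correction: bool = False) -> dict[str, Chi2Result]:
    """Tests on lineage-origin composition.

    ``counts`` is a marker x origin table of lineage counts (tests whether
    the origin composition differs between markers).  ``paired`` optionally
    holds one row per individual with columns ``mtDNA`` and ``MSY`` giving
    the two origin labels, testing within-individual association.
    """
    out = {"marker_vs_origin": chi2_independence(counts, correction=correction)}
    if paired is not None:
        tab = pd.crosstab(paired["mtDNA"], paired["MSY"])
        out["within_individual"] = chi2_independence(tab, correction=correction)
    return out
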