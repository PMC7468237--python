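"""Molecular diversity, pairwise distances, AMOVA and PhiST.

The analysis of molecular variance (AMOVA) decomposes the total molecular
variance computed from squared inter-haplotype distances into hierarchical
components: among groups (sigma2_a), among populations within groups
(sigma2_b) and within populations (sigma2_c).  From the components the
Phi-statistics follow:

    Phi_ST = (sigma2_a + sigma2_b) / sigma2_total   (one-level: sigma2_a / total)
    Phi_CT = sigma2_a / sigma2_total
    Phi_SC = sigma2_b / (sigma2_b + sigma2_c)

Distances enter as squared pairwise sequence differences (Arlequin
convention), so Phi_ST is the sequence-based fixation index usually written
as PhiST.  Significance is assessed by permutation: samples among
populations for Phi_ST, whole populations among groups for Phi_CT, samples
among populations within their group for Phi_SC, with the +1-smoothed
p-value (#null >= observed + 1) / (n_perm + 1).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, FormatError, MetadataError
from .sequence_io import HaploidAlignment, SampleTable

MISSING = ("N", "-")


@dataclass
class DistanceMatrix:
    """Symmetric nonnegative distance matrix with labels."""

    labels: list[str]
    values: np.ndarray
    metric: str = "pairwise-differences"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise FormatError("distance matrix shape does not match labels")
        if not np.allclose(self.values, self.values.T, equal_nan=True):
            raise FormatError("distance matrix is not symmetric")
        if np.any(np.diag(self.values) != 0):
            raise FormatError("distance matrix diagonal must be zero")

    @property
    def n(self) -> int:
        return len(self.labels)

    def submatrix(self, labels: Sequence[str]) -> "DistanceMatrix":
        idx = [self.labels.index(l) for l in labels]
        return DistanceMatrix(list(labels), self.values[np.ix_(idx, idx)], self.metric)

    def condensed(self) -> np.ndarray:
        """Upper-triangle entries in row-major order."""
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(self.values, index=self.labels, columns=self.labels).to_csv(
            path, sep="\t"
        )

    @classmethod
    def from_tsv(cls, path: str | Path, metric: str = "pairwise-differences"
                 ) -> "DistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(df.index.astype(str)), df.to_numpy(dtype=float), metric)


def pairwise_differences(aln: HaploidAlignment) -> DistanceMatrix:
    """Count of differing sites per sample pair; N/gap sites skipped pairwise."""
    if aln.n_samples < 2:
        raise DegenerateInputError("need at least two sequences")
    n = aln.n_samples
    D = np.zeros((n, n))
    # only columns with >=2 distinct valid states can contribute
    for j in range(aln.n_sites):
        col = aln.matrix[:, j]
        valid = ~np.isin(col, MISSING)
        states = np.unique(col[valid])
        if states.size < 2:
            continue
        both = valid[:, None] & valid[None, :]
        neq = col[:, None] != col[None, :]
        D += both & neq
    return DistanceMatrix(list(aln.sample_ids), D, "pairwise-differences")


# ---------------------------------------------------------------------------
# AMOVA


@dataclass
class AMOVAResult:
    """Variance decomposition with permutation significance.

    ``components`` holds the raw (possibly negative) estimates; percentages
    are computed after flooring negative components at zero (display
    convention of the standard software), and both views are kept.
    """

    design: str                       # "one-level" or "two-level"
    components: dict[str, float]      # sigma2_a (two-level only), sigma2_b, sigma2_c
    components_floored: dict[str, float]
    percentages: dict[str, float]     # from floored components, sum to 100
    phi: dict[str, float]             # Phi_ST (+ Phi_CT / Phi_SC when nested)
    p_values: dict[str, float]
    n_perm: int
    seed: int | None
    df: dict[str, int] = field(default_factory=dict)
    ss: dict[str, float] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for key in self.components:
            rows.append(
                {
                    "component": key,
                    "sigma2": self.components[key],
                    "sigma2_floored": self.components_floored[key],
                    "percent": self.percentages[key],
                }
            )
        return pd.DataFrame(rows)


def _check_partition(labels: np.ndarray) -> list[np.ndarray]:
    pops = []
    for p in pd.unique(labels):
        idx = np.where(labels == p)[0]
        if idx.size == 0:
            raise MetadataError(f"population {p!r} has no samples")
        pops.append(idx)
    if len(pops) < 2:
        raise DegenerateInputError("AMOVA needs at least two populations")
    return pops


def _ss_within(d2: np.ndarray, idx: np.ndarray) -> float:
    """Sum of squares within one set: sum_{i<j} d2 / n."""
    sub = d2[np.ix_(idx, idx)]
    return float(sub.sum()) / (2.0 * idx.size)


def _one_level(d2: np.ndarray, pops: list[np.ndarray]) -> dict:
    N = sum(p.size for p in pops)
    P = len(pops)
    ss_total = float(d2.sum()) / (2.0 * N)
    ss_wp = sum(_ss_within(d2, p) for p in pops)
    ss_ap = ss_total - ss_wp
    df_ap, df_wp = P - 1, N - P
    if df_wp == 0:
        raise DegenerateInputError("no within-population degrees of freedom")
    ms_ap, ms_wp = ss_ap / df_ap, ss_wp / df_wp
    n_c = (N - sum(p.size ** 2 for p in pops) / N) / df_ap
    sigma_c = ms_wp
    sigma_b = (ms_ap - ms_wp) / n_c
    total = sigma_b + sigma_c
    phi_st = sigma_b / total if total > 0 else 0.0
    return {
        "ss": {"among_populations": ss_ap, "within_populations": ss_wp, "total": ss_total},
        "df": {"among_populations": df_ap, "within_populations": df_wp},
        "components": {"among_populations": sigma_b, "within_populations": sigma_c},
        "phi": {"Phi_ST": phi_st},
    }


def _two_level(d2: np.ndarray, pops: list[np.ndarray],
               pop_groups: list[str]) -> dict:
    """Excoffier-style nested decomposition (groups / populations / samples)."""
    N = sum(p.size for p in pops)
    P = len(pops)
    group_names = list(dict.fromkeys(pop_groups))
    G = len(group_names)
    if G < 2:
        raise DegenerateInputError("two-level design needs at least two groups")
    groups = {
        g: np.concatenate([pops[i] for i in range(P) if pop_groups[i] == g])
        for g in group_names
    }
    ss_total = float(d2.sum()) / (2.0 * N)
    ss_wp = sum(_ss_within(d2, p) for p in pops)
    ss_wg = sum(_ss_within(d2, idx) for idx in groups.values())
    ss_ap_wg = ss_wg - ss_wp          # among populations within groups
    ss_ag = ss_total - ss_wg          # among groups
    df_ag, df_ap, df_wp = G - 1, P - G, N - P
    if df_ap <= 0:
        raise DegenerateInputError("need more populations than groups for a nested design")
    if df_wp == 0:
        raise DegenerateInputError("no within-population degrees of freedom")
    ms_ag, ms_ap, ms_wp = ss_ag / df_ag, ss_ap_wg / df_ap, ss_wp / df_wp

    sizes = {g: idx.size for g, idx in groups.items()}
    pop_sizes_by_group = {
        g: [pops[i].size for i in range(P) if pop_groups[i] == g] for g in group_names
    }
    sum_n2_over_g = sum(
        sum(s ** 2 for s in pop_sizes_by_group[g]) / sizes[g] for g in group_names
    )
    sum_n2 = sum(p.size ** 2 for p in pops)
    n1 = (N - sum_n2_over_g) / df_ap
    n2 = (sum_n2_over_g - sum_n2 / N) / df_ag
    n3 = (N - sum(s ** 2 for s in sizes.values()) / N) / df_ag

    sigma_c = ms_wp
    sigma_b = (ms_ap - sigma_c) / n1
    sigma_a = (ms_ag - sigma_c - n2 * sigma_b) / n3
    total = sigma_a + sigma_b + sigma_c
    phi_st = (sigma_a + sigma_b) / total if total > 0 else 0.0
    phi_ct = sigma_a / total if total > 0 else 0.0
    denom_sc = sigma_b + sigma_c
    phi_sc = sigma_b / denom_sc if denom_sc > 0 else 0.0
    return {
        "ss": {
            "among_groups": ss_ag,
            "among_populations_within_groups": ss_ap_wg,
            "within_populations": ss_wp,
            "total": ss_total,
        },
        "df": {
            "among_groups": df_ag,
            "among_populations_within_groups": df_ap,
            "within_populations": df_wp,
        },
        "components": {
            "among_groups": sigma_a,
            "among_populations_within_groups": sigma_b,
            "within_populations": sigma_c,
        },
        "phi": {"Phi_ST": phi_st, "Phi_CT": phi_ct, "Phi_SC": phi_sc},
    }


def _floor_percent(components: dict[str, float]) -> tuple[dict, dict]:
    floored = {k: max(v, 0.0) for k, v in components.items()}
    tot = sum(floored.values())
    if tot == 0:
        pct = {k: 0.0 for k in floored}
    else:
        pct = {k: 100.0 * v / tot for k, v in floored.items()}
    return floored, pct


def amova(dm: DistanceMatrix, populations: Sequence[str],
          groups: Sequence[str] | None = None, n_perm: int = 10_000,
          seed: int | None = None, exact: bool = False) -> AMOVAResult:
    """AMOVA on squared distances with permutation p-values.

    ``populations`` (and optionally ``groups``, one per sample, nesting the
    populations) are aligned with ``dm.labels``.  With ``exact=True`` the
    Phi_ST null is enumerated over all distinct label rearrangements
    (feasible for small n) and the p-value is the exact tail probability,
    identity permutation included.
    """
    populations = np.asarray(populations)
    if len(populations) != dm.n:
        raise MetadataError("one population label per distance-matrix row required")
    pops = _check_partition(populations)
    d2 = dm.values ** 2
    rng = np.random.default_rng(seed)

    if groups is None:
        fit = _one_level(d2, pops)
    else:
        groups = np.asarray(groups)
        pop_names = [str(populations[p[0]]) for p in pops]
        pop_groups = []
        for p in pops:
            g = set(groups[p])
            if len(g) != 1:
                raise MetadataError(
                    f"population {populations[p[0]]!r} spans multiple groups {sorted(g)}"
                )
            pop_groups.append(str(g.pop()))
        fit = _two_level(d2, pops, pop_groups)

    floored, pct = _floor_percent(fit["components"])
    p_values: dict[str, float] = {}
    obs_st = fit["phi"]["Phi_ST"]
    if exact:
        null = [
            _stat_for_perm(d2, populations, np.asarray(perm), groups)
            for perm in itertools.permutations(range(dm.n))
        ]
        p_values["Phi_ST"] = sum(v >= obs_st - 1e-12 for v in null) / len(null)
        n_used = len(null)
    else:
        count = 0
        for _ in range(n_perm):
            perm = rng.permutation(dm.n)
            if _stat_for_perm(d2, populations, perm, groups) >= obs_st - 1e-12:
                count += 1
        p_values["Phi_ST"] = (count + 1) / (n_perm + 1)
        n_used = n_perm

    if groups is not None and not exact:
        p_values["Phi_CT"] = _perm_phi_ct(d2, pops, populations, groups, fit, n_perm, rng)
        p_values["Phi_SC"] = _perm_phi_sc(d2, populations, groups, fit, n_perm, rng)

    return AMOVAResult(
        design="one-level" if groups is None else "two-level",
        components=fit["components"],
        components_floored=floored,
        percentages=pct,
        phi=fit["phi"],
        p_values=p_values,
        n_perm=n_used,
        seed=seed,
        df=fit["df"],
        ss=fit["ss"],
    )


def _stat_for_perm(d2: np.ndarray, populations: np.ndarray, perm: np.ndarray,
                   groups: Sequence[str] | None) -> float:
    """Phi_ST with samples permuted among populations (labels reshuffled)."""
    permuted = populations[perm]
    ps = [np.where(permuted == p)[0] for p in pd.unique(permuted)]
    if groups is None:
        return _one_level(d2, ps)["phi"]["Phi_ST"]
    pg = [str(np.asarray(groups)[perm][p[0]]) for p in ps]
    return _two_level(d2, ps, pg)["phi"]["Phi_ST"]


def _perm_phi_ct(d2, pops, populations, groups, fit, n_perm, rng) -> float:
    """Null for Phi_CT: permute whole populations among groups (keeping the
    number of populations per group fixed)."""
    pop_groups = [str(np.asarray(groups)[p[0]]) for p in pops]
    obs = fit["phi"]["Phi_CT"]
    count = 0
    for _ in range(n_perm):
        shuffled = list(rng.permutation(pop_groups))
        try:
            val = _two_level(d2, pops, shuffled)["phi"]["Phi_CT"]
        except DegenerateInputError:
            continue
        if val >= obs - 1e-12:
            count += 1
    return (count + 1) / (n_perm + 1)


def _perm_phi_sc(d2, populations, groups, fit, n_perm, rng) -> float:
    """Null for Phi_SC: permute samples among populations within their group."""
    groups = np.asarray(groups)
    obs = fit["phi"]["Phi_SC"]
    count = 0
    idx_by_group = {g: np.where(groups == g)[0] for g in pd.unique(groups)}
    for _ in range(n_perm):
        permuted = populations.copy()
        for idx in idx_by_group.values():
            permuted[idx] = permuted[idx][rng.permutation(idx.size)]
        ps = [np.where(permuted == p)[0] for p in pd.unique(permuted)]
        pg = [str(groups[p[0]]) for p in ps]
        try:
            val = _two_level(d2, ps, pg)["phi"]["Phi_SC"]
        except DegenerateInputError:
            continue
        if val >= obs - 1e-12:
            count += 1
    return (count + 1) / (n_perm + 1)


def amova_from_table(dm: DistanceMatrix, table: SampleTable, grouping: str,
                     n_perm: int = 10_000, seed: int | None = None) -> AMOVAResult:
    """AMOVA under one of the three study grouping scenarios.

    ``grouping='combined'`` runs a one-level design over the country-by-route
    populations; ``'country'`` and ``'route'`` run nested designs with the
    respective label as the group stratum above those populations.
    """
    pops = table.labels(dm.labels, "group")
    if grouping == "combined":
        return amova(dm, pops, None, n_perm=n_perm, seed=seed)
    if grouping in ("country", "route"):
        groups = table.labels(dm.labels, grouping)
        return amova(dm, pops, groups, n_perm=n_perm, seed=seed)
    raise MetadataError(f"unknown grouping scenario {grouping!r}")


# ---------------------------------------------------------------------------
# pairwise PhiST


def pairwise_phist(dm: DistanceMatrix, populations: Sequence[str]) -> DistanceMatrix:
    """Matrix of pairwise PhiST values over populations.

    Each entry is the among-population variance fraction of a two-population
    AMOVA on the corresponding sub-matrix.  Pairs where both populations
    have a single sample leave no within-population variance and are
    reported as NaN.  Slightly negative estimates are floored at zero so the
    result remains a distance-like matrix.
    """
    populations = np.asarray(populations)
    names = list(pd.unique(populations))
    if len(names) < 2:
        raise DegenerateInputError("need at least two populations")
    k = len(names)
    out = np.zeros((k, k))
    d2 = dm.values ** 2
    for a in range(k):
        for b in range(a + 1, k):
            ia = np.where(populations == names[a])[0]
            ib = np.where(populations == names[b])[0]
            if ia.size == 1 and ib.size == 1:
                out[a, b] = out[b, a] = np.nan
                continue
            idx = np.concatenate([ia, ib])
            sub = d2[np.ix_(idx, idx)]
            fit = _one_level(sub, [np.arange(ia.size), np.arange(ia.size, idx.size)])
            out[a, b] = out[b, a] = max(fit["phi"]["Phi_ST"], 0.0)
    return DistanceMatrix([str(n) for n in names], out, "phist")


# ---------------------------------------------------------------------------
# diversity summaries


@dataclass
class DiversitySummary:
    population: str
    n: int
    segregating_sites: int
    nucleotide_diversity: float     # mean pairwise differences per sequence pair
    haplotype_diversity: float
    ci: dict[str, tuple[float, float]]


def _summaries(matrix: np.ndarray) -> tuple[int, float, float]:
    n = matrix.shape[0]
    S = 0
    for j in range(matrix.shape[1]):
        col = matrix[:, j]
        states = np.unique(col[~np.isin(col, MISSING)])
        if states.size >= 2:
            S += 1
    total = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            valid = ~np.isin(matrix[i], MISSING) & ~np.isin(matrix[j], MISSING)
            total += np.sum((matrix[i] != matrix[j]) & valid)
    pi = total / (n * (n - 1) / 2)
    haps = ["".join(r) for r in matrix]
    freqs = pd.Series(haps).value_counts(normalize=True).to_numpy()
    h = n / (n - 1) * (1.0 - float(np.sum(freqs ** 2)))
    return S, pi, h


def diversity_summary(aln: HaploidAlignment, table: SampleTable | None = None,
                      n_boot: int = 1_000, seed: int | None = None
                      ) -> list[DiversitySummary]:
    """Per-population S, pi (mean pairwise differences), haplotype diversity
    h = n/(n-1) (1 - sum p_i^2), with percentile bootstrap CIs over samples."""
    rng = np.random.default_rng(seed)
    if table is None:
        strata = {"all": np.arange(aln.n_samples)}
    else:
        labels = table.labels(aln.sample_ids, "group")
        strata = {g: np.where(labels == g)[0] for g in pd.unique(labels)}
    out = []
    for name, idx in strata.items():
        if idx.size < 2:
            raise DegenerateInputError(f"population {name!r} has n < 2")
        sub = aln.matrix[idx]
        S, pi, h = _summaries(sub)
        boots = {"segregating_sites": [], "nucleotide_diversity": [],
                 "haplotype_diversity": []}
        for _ in range(n_boot):
            take = rng.integers(0, idx.size, size=idx.size)
            if np.unique(take).size < 2:
                take[1] = (take[0] + 1) % idx.size  # keep two distinct rows
            bS, bpi, bh = _summaries(sub[take])
            boots["segregating_sites"].append(bS)
            boots["nucleotide_diversity"].append(bpi)
            boots["haplotype_diversity"].append(bh)
        ci = {
            k: (float(np.percentile(v, 2.5)), float(np.percentile(v, 97.5)))
            for k, v in boots.items()
        }
        out.append(DiversitySummary(name, int(idx.size), S, pi, h, ci))
    return out


def subsample_balance(table: SampleTable, population: str, k: int,
                      seed: int | None = None) -> SampleTable:
    """Uniform random subset (without replacement) of ``k`` samples from one
    country-by-route population; used to balance sample sizes before AMOVA."""
    rng = np.random.default_rng(seed)
    df = table.df
    idx = df.index[df["group"] == population]
    if len(idx) == 0:
        raise MetadataError(f"no samples in population {population!r}")
    if k > len(idx):
        raise DegenerateInputError(
            f"cannot draw {k} from population of size {len(idx)}"
        )
    chosen = rng.choice(idx.to_numpy(), size=k, replace=False)
    sub = df.loc[np.sort(chosen)].drop(columns="group")
    return SampleTable(sub.reset_index(drop=True))
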