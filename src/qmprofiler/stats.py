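"""Concordance statistics for comparing profiling methods.

Richness, Bray-Curtis dissimilarity with principal-coordinates ordination,
within- vs between-method replicate dissimilarity testing, per-genus rank
concordance (Kendall tau-b), correlations, rank tests and
Benjamini-Hochberg FDR control.  All tests are two-sided by default.

The Wilcoxon signed-rank and Mann-Whitney U tests implement exact,
tie-aware null enumeration for small samples (via characteristic-function
style convolution over midranks, and direct enumeration of group
assignments, respectively) and fall back to the usual normal approximations
with tie and continuity corrections for larger samples.

Note Bray-Curtis is a dissimilarity, not a metric: it violates the
triangle inequality, so no metric property is asserted on it here.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, NamedTuple

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.spatial.distance import braycurtis as _bc_pair
from scipy.spatial.distance import pdist, squareform
import skbio
from skbio.stats.ordination import pcoa as _skbio_pcoa
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)


class TestResult(NamedTuple):
    statistic: float
    pvalue: float


class CorrelationResult(NamedTuple):
    coefficient: float
    pvalue: float


# ---------------------------------------------------------------------------
# richness and dissimilarity


def _as_matrix(profile) -> pd.DataFrame:
    """Accept a QuantProfile, TaxonCountTable or DataFrame (taxa x samples)."""
    if hasattr(profile, "abundances"):
        return profile.abundances
    if hasattr(profile, "counts"):
        return profile.counts
    return pd.DataFrame(profile)


def observed_richness(profile) -> pd.Series:
    """Per-sample count of taxa with abundance > 0 (scale invariant)."""
    mat = _as_matrix(profile)
    return (mat > 0).sum(axis=0).astype(int)


def bray_curtis_pair(x, y) -> float:
    """Bray-Curtis dissimilarity ``sum|x-y| / sum(x+y)`` of two vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if (x < 0).any() or (y < 0).any():
        raise ValueError("Bray-Curtis requires non-negative abundances")
    if x.sum() == 0 and y.sum() == 0:
        log.warning("Bray-Curtis on two all-zero vectors; returning 0")
        return 0.0
    return float(_bc_pair(x, y))


def bray_curtis_matrix(profile, normalize: bool = False) -> skbio.DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarities between samples.

    ``normalize=True`` converts columns to proportions first (relevant for
    quantitative profiles, where the default operates on absolute
    cells/gram abundances).
    """
    mat = _as_matrix(profile)
    if (mat.to_numpy() < 0).any():
        raise ValueError("Bray-Curtis requires non-negative abundances")
    data = mat.to_numpy(dtype=float).T  # samples x taxa
    if normalize:
        sums = data.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore"):
            data = np.where(sums > 0, data / np.where(sums == 0, 1, sums), 0.0)
    zero_rows = data.sum(axis=1) == 0
    if zero_rows.any():
        log.warning(
            "all-zero samples in Bray-Curtis input: %s",
            list(mat.columns[zero_rows]),
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        condensed = pdist(data, metric="braycurtis")
    condensed = np.nan_to_num(condensed, nan=0.0)  # both-zero pairs -> 0
    return skbio.DistanceMatrix(squareform(condensed), ids=list(mat.columns))


def pcoa(distance_matrix, number_of_dimensions: int = 0):
    """Classical metric scaling (principal coordinates analysis).

    Thin wrapper around scikit-bio: double-center ``-D^2/2``,
    eigendecompose, take coordinates from the positive eigenvalues.
    Negative eigenvalues (non-Euclidean input) are reported in
    ``.eigvals`` rather than corrected.
    """
    if not isinstance(distance_matrix, skbio.DistanceMatrix):
        distance_matrix = skbio.DistanceMatrix(np.asarray(distance_matrix, float))
    with warnings.catch_warnings():
        warnings.filterwarnings(
            "ignore", message=".*negative eigenvalues.*", category=RuntimeWarning
        )
        return _skbio_pcoa(
            distance_matrix, method="eigh",
            number_of_dimensions=number_of_dimensions,
        )


# ---------------------------------------------------------------------------
# replicate dissimilarity analysis


@dataclass
class DissimilarityReport:
    """Within-/between-method Bray-Curtis distances and their comparisons.

    ``distances`` maps a group label (``within:<method>`` or
    ``between:<a>|<b>``) to a per-subject Series; ``summary`` holds medians
    and quartiles; ``tests`` the paired-Wilcoxon comparisons with BH
    adjustment across all comparisons.
    """

    distances: dict
    summary: pd.DataFrame
    tests: pd.DataFrame


def _split_sample_id(sid: str) -> tuple[str, str]:
    if "_r" not in sid:
        raise ValueError(f"sample id {sid!r} not of form <subject>_r<replicate>")
    subject, rep = sid.rsplit("_r", 1)
    return subject, rep


def replicate_dissimilarity_analysis(
    profiles: Mapping[str, object], normalize: bool = False
) -> DissimilarityReport:
    """Compare replicate variation within and between profiling methods.

    Within-method distance: Bray-Curtis between a subject's two replicates
    under one method.  Between-method distance: replicate-matched BC
    between the same subject's profiles under two methods, averaged over
    the two replicates.  All groups are compared pairwise with the paired
    Wilcoxon signed-rank test (paired by subject) and BH-adjusted.
    """
    mats = {m: _as_matrix(p) for m, p in profiles.items()}
    if len(mats) < 1:
        raise ValueError("at least one profile is required")
    if normalize:
        mats = {m: v / v.sum(axis=0) for m, v in mats.items()}

    subjects: dict[str, dict[str, str]] = {}
    ref_cols = None
    for method, mat in mats.items():
        cols = sorted(mat.columns)
        if ref_cols is None:
            ref_cols = cols
        elif cols != ref_cols:
            raise ValueError("profiles must share identical sample ids")
    assert ref_cols is not None
    for sid in ref_cols:
        subject, rep = _split_sample_id(sid)
        subjects.setdefault(subject, {})[rep] = sid
    for subject, reps in subjects.items():
        if len(reps) != 2:
            raise ValueError(f"subject {subject} does not have exactly 2 replicates")

    subject_ids = sorted(subjects)
    distances: dict[str, pd.Series] = {}
    for method, mat in mats.items():
        vals = []
        for subject in subject_ids:
            (r1, s1), (r2, s2) = sorted(subjects[subject].items())
            vals.append(bray_curtis_pair(mat[s1], mat[s2]))
        distances[f"within:{method}"] = pd.Series(vals, index=subject_ids)
    for a, b in itertools.combinations(mats, 2):
        vals = []
        for subject in subject_ids:
            pair_vals = [
                bray_curtis_pair(mats[a][sid], mats[b][sid])
                for rep, sid in sorted(subjects[subject].items())
            ]
            vals.append(float(np.mean(pair_vals)))
        distances[f"between:{a}|{b}"] = pd.Series(vals, index=subject_ids)

    summary = pd.DataFrame(
        {
            "median": {g: s.median() for g, s in distances.items()},
            "q1": {g: s.quantile(0.25) for g, s in distances.items()},
            "q3": {g: s.quantile(0.75) for g, s in distances.items()},
        }
    )

    rows = []
    for g1, g2 in itertools.combinations(distances, 2):
        try:
            res = paired_wilcoxon(distances[g1].to_numpy(), distances[g2].to_numpy())
            stat, p = res.statistic, res.pvalue
        except ValueError:  # identical groups: no nonzero differences
            stat, p = np.nan, 1.0
        rows.append((g1, g2, stat, p))
    tests = pd.DataFrame(rows, columns=["group1", "group2", "statistic", "pvalue"])
    if len(tests):
        tests["pvalue_bh"] = bh_adjust(tests["pvalue"].to_numpy())
    return DissimilarityReport(distances=distances, summary=summary, tests=tests)


# ---------------------------------------------------------------------------
# rank concordance


def top_genus_rank_concordance(
    profile_a, profile_b, reference, n_top: int = 15
) -> pd.DataFrame:
    """Per-genus Kendall tau-b between two methods on the top genera.

    The ``n_top`` genera are chosen by mean relative abundance in the
    reference profile; for each, tau-b is computed between the two
    methods' across-sample abundance vectors.  Degenerate (constant)
    vectors yield NaN.
    """
    a, b, ref = (_as_matrix(p) for p in (profile_a, profile_b, reference))
    if not (list(a.columns) == list(b.columns)):
        b = b[a.columns]
    if n_top > len(ref.index):
        raise ValueError("n_top exceeds the number of taxa")
    ref_rel = ref / ref.sum(axis=0)
    top = ref_rel.mean(axis=1).sort_values(ascending=False).index[:n_top]
    rows = []
    for genus in top:
        x = a.loc[genus].to_numpy(dtype=float)
        y = b.loc[genus].to_numpy(dtype=float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            rows.append((genus, np.nan, np.nan))
            continue
        tau, p = sps.kendalltau(x, y, variant="b")
        rows.append((genus, float(tau), float(p)))
    return pd.DataFrame(rows, columns=["genus", "tau", "pvalue"]).set_index("genus")


# ---------------------------------------------------------------------------
# correlations


def correlate(x, y, method: str = "pearson") -> CorrelationResult:
    """Pearson or Spearman correlation with a two-sided p-value.

    Spearman p-values come from exact permutation enumeration for n <= 9
    and the t-approximation above.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("length mismatch")
    n = x.size
    if n < 3:
        raise ValueError("at least 3 observations are required")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance input")
    if method == "pearson":
        r, p = sps.pearsonr(x, y)
        return CorrelationResult(float(r), float(p))
    if method != "spearman":
        raise ValueError("method must be 'pearson' or 'spearman'")
    xr = sps.rankdata(x)
    yr = sps.rankdata(y)
    rho = float(np.corrcoef(xr, yr)[0, 1])
    if n <= 9:
        p = _exact_spearman_p(xr, yr, rho)
    else:
        rho_s, p = sps.spearmanr(x, y)
        p = float(p)
    return CorrelationResult(rho, float(p))


def _exact_spearman_p(xr: np.ndarray, yr: np.ndarray, rho_obs: float) -> float:
    """Two-sided permutation p-value for Spearman rho (small n, tie-aware)."""
    n = xr.size
    perms = np.array(list(itertools.permutations(range(n))))
    xc = xr - xr.mean()
    yc = yr - yr.mean()
    denom = np.sqrt((xc**2).sum() * (yc**2).sum())
    rhos = (yc[perms] @ xc) / denom
    return float(np.mean(np.abs(rhos) >= abs(rho_obs) - 1e-12))


# ---------------------------------------------------------------------------
# rank tests


def _signed_rank_distribution(doubled_ranks: np.ndarray) -> np.ndarray:
    """Null distribution of 2*W+ over all sign assignments (convolution).

    Midranks are multiples of 1/2, so doubling makes them integers; the
    returned array ``c`` has ``c[w]`` = number of sign vectors with
    ``2*W+ == w``.  Handles ties exactly.
    """
    total = int(doubled_ranks.sum())
    coef = np.zeros(total + 1, dtype=float)
    coef[0] = 1.0
    for r in doubled_ranks:
        r = int(r)
        new = coef.copy()
        new[r:] += coef[: total + 1 - r]
        coef = new
    return coef


def paired_wilcoxon(x, y) -> TestResult:
    """Two-sided paired Wilcoxon signed-rank test.

    Zero differences are dropped.  For n <= 20 the null is enumerated
    exactly (tie-aware); above that a normal approximation with tie and
    continuity corrections is used.  The statistic is ``W+``, the sum of
    ranks of positive differences.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("length mismatch")
    d = x - y
    d = d[d != 0]
    n = d.size
    if n == 0:
        raise ValueError("all differences are zero")
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= 20:
        doubled = np.round(2 * ranks).astype(int)
        dist = _signed_rank_distribution(doubled)
        w2 = int(round(2 * w_plus))
        total = 2.0**n
        cdf = dist[: w2 + 1].sum() / total
        sf = dist[w2:].sum() / total
        p = min(1.0, 2.0 * min(cdf, sf))
    else:
        mean = n * (n + 1) / 4.0
        var = n * (n + 1) * (2 * n + 1) / 24.0
        _, tie_counts = np.unique(ranks, return_counts=True)
        var -= (tie_counts**3 - tie_counts).sum() / 48.0
        diff = w_plus - mean
        z = (diff - 0.5 * np.sign(diff)) / np.sqrt(var)
        p = min(1.0, 2.0 * sps.norm.sf(abs(z)))
    return TestResult(w_plus, float(p))


def mann_whitney_u(group1, group2) -> TestResult:
    """Two-sided Mann-Whitney U test.

    Exact tie-aware enumeration of group assignments for pooled n <= 14;
    normal approximation with tie and continuity corrections otherwise.
    The statistic is ``U1`` for the first group.
    """
    g1 = np.asarray(group1, dtype=float)
    g2 = np.asarray(group2, dtype=float)
    n1, n2 = g1.size, g2.size
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([g1, g2])
    ranks = sps.rankdata(pooled)
    r1 = ranks[:n1].sum()
    u1 = float(r1 - n1 * (n1 + 1) / 2.0)
    if n1 + n2 <= 14:
        combos = np.array(
            list(itertools.combinations(range(n1 + n2), n1)), dtype=np.intp
        )
        sums = ranks[combos].sum(axis=1)
        u_all = sums - n1 * (n1 + 1) / 2.0
        m = u_all.size
        cdf = np.sum(u_all <= u1 + 1e-9) / m
        sf = np.sum(u_all >= u1 - 1e-9) / m
        p = min(1.0, 2.0 * min(cdf, sf))
    else:
        mean = n1 * n2 / 2.0
        _, tie_counts = np.unique(ranks, return_counts=True)
        nt = n1 + n2
        tie_term = (tie_counts**3 - tie_counts).sum() / (nt * (nt - 1))
        var = n1 * n2 / 12.0 * (nt + 1 - tie_term)
        diff = u1 - mean
        z = (diff - 0.5 * np.sign(diff)) / np.sqrt(var)
        p = min(1.0, 2.0 * sps.norm.sf(abs(z)))
    return TestResult(u1, float(p))


# ---------------------------------------------------------------------------
# multiple testing


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]
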