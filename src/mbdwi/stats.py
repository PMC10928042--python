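"""Group-comparison statistics for the imaging–histology study.

The analysis layer mirrors a small-animal treatment study: Spearman rank
correlations (with a graded |r| interpretation), a Kruskal–Wallis omnibus
test across treatment groups, Bonferroni-adjusted pairwise Mann–Whitney U
tests reported as tie-corrected normal-approximation Z (no continuity
correction), and intraclass correlation coefficients for observer
agreement.  ``analyze_study`` assembles the full report from a per-subject
study table.

Conventions:

* Spearman p is exact (full permutation enumeration) for n ≤ 9 and the
  t-approximation otherwise.
* Bonferroni: p_adj = min(1, p × m) with m = number of pairwise tests.
* ICC defaults to the two-way random-effects, absolute-agreement,
  single-measure form ICC(2,1); ICC(3,1) is selectable.
* Two-sided tests throughout; significance threshold 0.05.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations, permutations

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "CorrelationResult", "MannWhitneyResult", "IccResult",
    "spearman", "classify_correlation", "classify_icc",
    "kruskal_wallis", "mann_whitney", "pairwise_mann_whitney", "icc",
    "analyze_study", "StudyReport",
    "GROUP_LABELS", "DWI_COLUMNS", "HISTO_COLUMNS",
]

GROUP_LABELS = ("BS", "B", "S", "C")
DWI_COLUMNS = ("D_t", "D_p", "f", "MD", "MK", "DDC", "alpha", "D", "beta", "mu")
HISTO_COLUMNS = ("volume", "NF", "MVD", "SD")

ALPHA_LEVEL = 0.05


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p: float
    grade: str
    n: int


@dataclass(frozen=True)
class MannWhitneyResult:
    u: float
    z: float
    p: float
    p_adjusted: float


@dataclass(frozen=True)
class IccResult:
    icc: float
    ci95: tuple[float, float]
    p: float
    grade: str


def classify_correlation(r: float) -> str:
    """Graded interpretation of |r|.

    0 ≤ |r| < 0.2 poor-to-no; 0.2 ≤ |r| ≤ 0.4 fair; 0.4 < |r| ≤ 0.6
    moderate; 0.6 < |r| ≤ 0.8 good; |r| > 0.8 excellent.
    """
    a = abs(r)
    if a > 1:
        raise ValueError("|r| cannot exceed 1")
    if a < 0.2:
        return "poor-to-no relationship"
    if a <= 0.4:
        return "fair relationship"
    if a <= 0.6:
        return "moderate relationship"
    if a <= 0.8:
        return "good relationship"
    return "excellent relationship"


def classify_icc(value: float) -> str:
    """ICC reliability bands: ≤0.40 poor-to-fair; 0.41–0.60 moderate;
    0.61–0.80 good; >0.80 excellent."""
    if value <= 0.40:
        return "poor-to-fair reliability"
    if value <= 0.60:
        return "moderate reliability"
    if value <= 0.80:
        return "good reliability"
    return "excellent reliability"


def _spearman_rho(x: np.ndarray, y: np.ndarray) -> float:
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    return float(np.corrcoef(rx, ry)[0, 1])


def spearman(x, y, exact_max_n: int = 9) -> CorrelationResult:
    """Spearman rank correlation with mid-ranked ties.

    Two-sided p by exhaustive permutation of one margin for n ≤
    ``exact_max_n``, t-approximation otherwise.  Pairs with missing values
    are dropped; a constant margin raises (rho undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 complete pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("rho undefined for a constant vector")

    rho = _spearman_rho(x, y)
    if n <= exact_max_n:
        ry = sps.rankdata(y)
        rx = sps.rankdata(x)
        obs = abs(rho)
        count = 0
        total = 0
        for perm in permutations(ry):
            r = np.corrcoef(rx, np.asarray(perm))[0, 1]
            if abs(r) >= obs - 1e-12:
                count += 1
            total += 1
        p = count / total
    else:
        t = rho * math.sqrt((n - 2) / max(1.0 - rho * rho, 1e-15))
        p = float(2 * sps.t.sf(abs(t), df=n - 2))
    return CorrelationResult(r=rho, p=min(p, 1.0), grade=classify_correlation(rho), n=n)


def kruskal_wallis(groups) -> tuple[float, float]:
    """Tie-corrected Kruskal–Wallis H and its χ²(k−1) p-value.

    All-identical data across all groups is a degenerate case of the tie
    correction and returns (0, 1) explicitly.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(g.size < 1 for g in groups):
        raise ValueError("need >=2 non-empty groups")
    pooled = np.concatenate(groups)
    if pooled.size < 3:
        raise ValueError("need a total n of at least 3")
    if np.ptp(pooled) == 0:
        return 0.0, 1.0
    h, p = sps.kruskal(*groups)
    return float(h), float(p)


def _tie_corrected_sigma_u(n1: int, n2: int, pooled: np.ndarray) -> float:
    n = n1 + n2
    _, t = np.unique(pooled, return_counts=True)
    tie_term = ((t ** 3 - t).sum()) / (n * (n - 1)) if n > 1 else 0.0
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    return math.sqrt(var)


def _exact_mw_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided exact Mann–Whitney p by enumerating group assignments."""
    pooled = np.concatenate([x, y])
    n1 = x.size
    ranks = sps.rankdata(pooled)
    u_obs = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)
    mu = n1 * y.size / 2.0
    dev_obs = abs(u_obs - mu)
    count = 0
    total = 0
    idx_all = range(pooled.size)
    for comb in combinations(idx_all, n1):
        u = float(ranks[list(comb)].sum() - n1 * (n1 + 1) / 2.0)
        if abs(u - mu) >= dev_obs - 1e-12:
            count += 1
        total += 1
    return count / total


def mann_whitney(x, y, exact: bool = False) -> MannWhitneyResult:
    """Mann–Whitney U with tie-corrected Z (no continuity correction).

    Z is signed by the direction of the first group's rank sum; p is
    two-sided from the normal approximation, or from exhaustive enumeration
    when ``exact`` (intended for n1 + n2 ≤ ~12).  ``p_adjusted`` equals the
    raw p here; use :func:`pairwise_mann_whitney` for Bonferroni.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x = x[np.isfinite(x)]
    y = y[np.isfinite(y)]
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    u1 = float(ranks[: x.size].sum() - x.size * (x.size + 1) / 2.0)
    mu = x.size * y.size / 2.0
    if np.ptp(pooled) == 0:
        return MannWhitneyResult(u=u1, z=0.0, p=1.0, p_adjusted=1.0)
    sigma = _tie_corrected_sigma_u(x.size, y.size, pooled)
    z = (u1 - mu) / sigma
    if exact:
        p = _exact_mw_p(x, y)
    else:
        p = float(2 * sps.norm.sf(abs(z)))
    return MannWhitneyResult(u=u1, z=float(z), p=min(p, 1.0), p_adjusted=min(p, 1.0))


def bonferroni(p: float, m: int) -> float:
    """p_adj = min(1, p·m); never below the raw p."""
    if not 0 <= p <= 1 or m < 1:
        raise ValueError("invalid p or m")
    return min(1.0, p * m)


def pairwise_mann_whitney(
    groups: dict[str, np.ndarray],
    pairs: list[tuple[str, str]] | None = None,
    m_comparisons: int | None = None,
    exact: bool = False,
) -> dict[tuple[str, str], MannWhitneyResult]:
    """Bonferroni-adjusted pairwise Mann–Whitney tests.

    ``pairs`` defaults to all label pairs in ``groups`` order; the Bonferroni
    multiplier defaults to the number of pairs actually tested (6 for four
    groups).
    """
    labels = list(groups)
    if pairs is None:
        pairs = list(combinations(labels, 2))
    m = m_comparisons if m_comparisons is not None else len(pairs)
    out = {}
    for a, b in pairs:
        res = mann_whitney(groups[a], groups[b], exact=exact)
        out[(a, b)] = MannWhitneyResult(
            u=res.u, z=res.z, p=res.p, p_adjusted=bonferroni(res.p, m)
        )
    return out


def icc(ratings: np.ndarray, model: str = "icc2") -> IccResult:
    """Intraclass correlation for a subjects × raters matrix.

    ``model='icc2'`` (default) is the two-way random-effects, absolute-
    agreement, single-measure ICC(2,1); ``'icc3'`` the two-way mixed,
    consistency, single-measure ICC(3,1).  The 95% CI and p come from the
    standard F-based intervals.  Zero between-subject variance leaves the
    coefficient undefined and raises.
    """
    ratings = np.asarray(ratings, dtype=float)
    if ratings.ndim != 2 or ratings.shape[0] < 5 or ratings.shape[1] < 2:
        raise ValueError("need a (>=5 subjects) x (>=2 raters) matrix")
    if np.ptp(ratings.mean(axis=1)) == 0:
        raise ValueError("ICC undefined: zero between-subject variance")
    n, k = ratings.shape
    frame = pd.DataFrame({
        "subject": np.repeat(np.arange(n), k),
        "rater": np.tile(np.arange(k), n),
        "score": ratings.ravel(),
    })
    import pingouin as pg  # deferred: heavy import

    table = pg.intraclass_corr(data=frame, targets="subject", raters="rater",
                               ratings="score")
    # absolute-agreement single measure = ICC(2,1); consistency = ICC(3,1)
    label = "ICC(A,1)" if model == "icc2" else "ICC(C,1)"
    row = table.set_index("Type").loc[label]
    value = float(row["ICC"])
    ci_col = "CI95%" if "CI95%" in table.columns else "CI95"
    lo, hi = (float(v) for v in row[ci_col])
    return IccResult(icc=value, ci95=(lo, hi), p=float(row["pval"]),
                     grade=classify_icc(value))


# --- study-level report ----------------------------------------------------

@dataclass
class StudyReport:
    """Tables assembled from a study: correlations, group summary, pairwise."""

    correlations: pd.DataFrame
    group_comparison: pd.DataFrame
    pairwise: pd.DataFrame

    def significant_correlations(self) -> pd.DataFrame:
        return self.correlations[self.correlations["p"] < ALPHA_LEVEL]

    def to_csv(self, out_dir) -> None:
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.correlations.to_csv(out / "correlations.csv", index=False)
        self.group_comparison.to_csv(out / "group_comparison.csv", index=False)
        self.pairwise.to_csv(out / "pairwise.csv", index=False)


def analyze_study(table: pd.DataFrame) -> StudyReport:
    """Full statistical report from a per-subject study table.

    The table needs a ``group`` column (labels from BS/B/S/C) plus the DWI
    parameter and histology columns.  Produces (1) Spearman correlations of
    each DWI parameter with volume/NF/MVD/SD, (2) per-group mean ± SD with
    the Kruskal–Wallis omnibus, (3) Bonferroni-adjusted pairwise
    Mann–Whitney Z and p for every variable.
    """
    required = ["group", *DWI_COLUMNS, *HISTO_COLUMNS]
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise ValueError(f"study table is missing columns: {missing}")
    bad = set(table["group"]) - set(GROUP_LABELS)
    if bad:
        raise ValueError(f"unknown group labels: {sorted(bad)}")

    corr_rows = []
    for param in DWI_COLUMNS:
        for target in HISTO_COLUMNS:
            res = spearman(table[param], table[target])
            corr_rows.append({"parameter": param, "target": target,
                              "r": res.r, "p": res.p, "grade": res.grade,
                              "n": res.n})
    correlations = pd.DataFrame(corr_rows)

    present = [g for g in GROUP_LABELS if (table["group"] == g).any()]
    variables = [*DWI_COLUMNS, *HISTO_COLUMNS]
    grp_rows = []
    pair_rows = []
    for var in variables:
        groups = {g: table.loc[table["group"] == g, var].to_numpy() for g in present}
        h, p = kruskal_wallis(list(groups.values()))
        row = {"variable": var, "H": h, "p": p}
        for g in present:
            row[f"{g}_mean"] = float(np.nanmean(groups[g]))
            row[f"{g}_sd"] = float(np.nanstd(groups[g], ddof=1)) if groups[g].size > 1 else 0.0
        grp_rows.append(row)

        for (a, b), res in pairwise_mann_whitney(groups).items():
            pair_rows.append({"variable": var, "pair": f"({a})-({b})",
                              "Z": res.z, "p_adjusted": res.p_adjusted,
                              "significant": res.p_adjusted < ALPHA_LEVEL})

    return StudyReport(
        correlations=correlations,
        group_comparison=pd.DataFrame(grp_rows),
        pairwise=pd.DataFrame(pair_rows),
    )
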