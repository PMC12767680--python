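"""Co-occurrence statistics for additive presence–absence data.

The inferential core is an exact multi-set intersection test: under the
null that m additives occur independently across the N products of a food
group, conditional on their marginal counts, the number of products
carrying all m additives is distributed as the intersection size of m
independent uniformly random fixed-size subsets of the N products.  That
distribution is built exactly by chaining hypergeometric steps
(``null_intersection_distribution``); two-sided p-values against it use
Blaker's acceptability construction so both over- and under-represented
combinations can be flagged.  Effect size is fold enrichment,
observed / (N·∏ sizes_i/N), with percentile bootstrap intervals on the log
scale obtained by resampling products within the group.

Descriptive outputs — additive-count histograms, per-group prevalence,
exact-combination (UpSet-style) counts and Spearman correlations between
additive count and nutrient content — live here too, emitted as tidy
DataFrames.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

from .lexicon import lump

__all__ = [
    "PresenceMatrix",
    "NullDistribution",
    "EnrichmentResult",
    "build_presence_matrix",
    "ets_count_distribution",
    "prevalence_table",
    "exact_combination_counts",
    "null_intersection_distribution",
    "blaker_two_sided_p",
    "bootstrap_ci_logfe",
    "enrichment_scan",
    "spearman_ets_nutrients",
]

#: float slack multiplier absorbing ties in the Blaker acceptability compare
BLAKER_TIE_SLACK = 1e-7


@dataclass
class PresenceMatrix:
    """Binary product × additive matrix, optionally restricted to one group."""

    data: pd.DataFrame  # bool, index = product ids, columns = codes
    groups: pd.Series | None = None  # per-product food group, aligned
    group: str | None = None  # restriction applied, if any

    @property
    def products(self) -> pd.Index:
        return self.data.index

    @property
    def codes(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n(self) -> int:
        return len(self.data)

    def column_sums(self) -> pd.Series:
        return self.data.sum(axis=0)

    def restrict(self, group: str) -> "PresenceMatrix":
        if self.groups is None:
            raise ValueError("matrix carries no group labels")
        mask = self.groups == group
        return PresenceMatrix(
            data=self.data.loc[mask.values],
            groups=self.groups[mask.values],
            group=group,
        )

    def lumped(self) -> "PresenceMatrix":
        """Collapse columns onto lump groups (presence = any member present)."""
        mapping = {c: lump(c) for c in self.data.columns}
        collapsed = self.data.T.groupby(mapping).any().T
        return PresenceMatrix(data=collapsed, groups=self.groups, group=self.group)


def build_presence_matrix(
    products: pd.DataFrame,
    codes: list[str] | None = None,
    lumped: bool = False,
) -> PresenceMatrix:
    """Build the presence matrix from a products frame with ``ets_codes`` sets."""
    sets = products["ets_codes"]
    if codes is None:
        codes = sorted(set().union(*sets) if len(sets) else set())
    arr = np.zeros((len(products), len(codes)), dtype=bool)
    idx = {c: j for j, c in enumerate(codes)}
    for i, s in enumerate(sets):
        for c in s:
            j = idx.get(c)
            if j is not None:
                arr[i, j] = True
    data = pd.DataFrame(arr, index=products.index, columns=codes)
    groups = products["group"] if "group" in products.columns else None
    pm = PresenceMatrix(data=data, groups=groups)
    return pm.lumped() if lumped else pm


# ---------------------------------------------------------------------------
# descriptive summaries
# ---------------------------------------------------------------------------

def _cap_labels(cap: int) -> list[str]:
    return [str(k) for k in range(cap)] + [f"{cap}+"]


def ets_count_distribution(
    products: pd.DataFrame, cap: int = 10, by: str | None = None
) -> pd.DataFrame:
    """Histogram of per-product additive counts, capped at ``cap``+ .

    ``by`` may name a column ("group", "hp_class") for stratified tallies;
    the result is tidy with columns [by?, n_ets, count].
    """
    capped = products["n_ets"].clip(upper=cap)
    labels = pd.Categorical(
        [f"{cap}+" if v >= cap else str(int(v)) for v in capped],
        categories=_cap_labels(cap),
    )
    frame = pd.DataFrame({"n_ets": labels})
    if by is not None:
        frame[by] = products[by].values
        out = (
            frame.groupby([by, "n_ets"], observed=False)
            .size()
            .rename("count")
            .reset_index()
        )
    else:
        out = frame.groupby("n_ets", observed=False).size().rename("count").reset_index()
    return out


def prevalence_table(matrix: PresenceMatrix) -> pd.DataFrame:
    """Percent of products carrying each code, per food group (tidy)."""
    if matrix.groups is None:
        raise ValueError("prevalence table needs group labels")
    rows = []
    for grp, sub in matrix.data.groupby(matrix.groups.values):
        n = len(sub)
        if n == 0:
            warnings.warn(f"empty food group {grp!r} omitted from prevalence table")
            continue
        for code, count in sub.sum(axis=0).items():
            rows.append(
                {
                    "group": grp,
                    "code": code,
                    "n_group": n,
                    "n_with_code": int(count),
                    "prevalence_pct": 100.0 * count / n,
                }
            )
    return pd.DataFrame(rows)


def exact_combination_counts(
    matrix: PresenceMatrix, min_products: int = 50
) -> pd.DataFrame:
    """Counts of *exact* additive sets (UpSet semantics), by food group.

    A product contributes to the one combination equal to its full additive
    set; products without additives are skipped.  Combinations carried by
    fewer than ``min_products`` products in total are dropped.
    """
    arr = matrix.data.values
    codes = np.asarray(matrix.codes, dtype=object)
    keys = [frozenset(codes[row]) for row in arr]
    groups = (
        matrix.groups.values
        if matrix.groups is not None
        else np.array(["all"] * len(keys), dtype=object)
    )
    frame = pd.DataFrame({"combo": keys, "group": groups})
    frame = frame[frame["combo"].map(len) > 0]
    if frame.empty:
        return pd.DataFrame(columns=["combo", "group", "count", "combo_total"])
    tidy = frame.groupby(["combo", "group"], observed=True).size().rename("count").reset_index()
    totals = tidy.groupby("combo", observed=True)["count"].transform("sum")
    tidy["combo_total"] = totals
    tidy = tidy[tidy["combo_total"] >= min_products]
    tidy["combo"] = tidy["combo"].map(lambda s: "&".join(sorted(s)))
    return tidy.sort_values(
        ["combo_total", "combo", "group"], ascending=[False, True, True]
    ).reset_index(drop=True)


# ---------------------------------------------------------------------------
# exact null distribution and Blaker two-sided p-value
# ---------------------------------------------------------------------------

@dataclass
class NullDistribution:
    """Exact pmf of the m-way intersection size under independence."""

    support: np.ndarray  # integers 0..min(sizes)
    pmf: np.ndarray
    n: int = 0
    sizes: tuple[int, ...] = field(default_factory=tuple)

    def mean(self) -> float:
        return float(np.dot(self.support, self.pmf))


def _hypergeom_transition(N: int, s_max: int, t: int, k_max: int) -> np.ndarray:
    """Matrix [s, k] = P(Hypergeom(N, s, t) = k), via log-gamma for speed.

    pmf(k) = C(s, k) C(N - s, t - k) / C(N, t); entries outside the valid
    range (k > s, t - k > N - s) are zero.
    """
    s = np.arange(s_max + 1)[:, None].astype(float)
    k = np.arange(k_max + 1)[None, :].astype(float)
    lg = gammaln
    with np.errstate(invalid="ignore"):
        logp = (
            lg(s + 1) - lg(k + 1) - lg(s - k + 1)
            + lg(N - s + 1) - lg(t - k + 1) - lg(N - s - (t - k) + 1)
            - (lg(N + 1) - lg(t + 1) - lg(N - t + 1))
        )
    valid = (k <= s) & (t - k <= N - s) & (k >= 0) & (t - k >= 0)
    out = np.zeros_like(logp)
    out[valid] = np.exp(logp[valid])
    return out


def null_intersection_distribution(N: int, sizes: list[int]) -> NullDistribution:
    """Exact distribution of |A1 ∩ … ∩ Am| for independent random subsets.

    Each A_i is a uniformly random size_i-subset of a common background of
    N products.  The pmf is computed by dynamic programming: start from a
    point mass at size_1, then fold in each further subset with a
    hypergeometric step (the overlap of a fixed s-subset with a random
    t-subset of N items is Hypergeometric(N, s, t)).
    """
    if N <= 0:
        raise ValueError("N must be positive")
    sizes = [int(s) for s in sizes]
    if len(sizes) < 2:
        raise ValueError("need at least two set sizes")
    for s in sizes:
        if s < 0 or s > N:
            raise ValueError(f"set size {s} outside [0, {N}]")

    cur_max = sizes[0]
    cur = np.zeros(cur_max + 1)
    cur[cur_max] = 1.0
    for t in sizes[1:]:
        new_max = min(cur_max, t)
        trans = _hypergeom_transition(N, cur_max, t, new_max)
        cur = cur @ trans
        cur_max = new_max
    cur = np.clip(cur, 0.0, None)
    total = cur.sum()
    if not math.isclose(total, 1.0, rel_tol=0, abs_tol=1e-9):
        cur = cur / total
    return NullDistribution(
        support=np.arange(cur_max + 1), pmf=cur, n=N, sizes=tuple(sizes)
    )


def blaker_two_sided_p(dist: NullDistribution, observed: int) -> float:
    """Two-sided exact p-value by Blaker's acceptability construction.

    With acceptability γ(x) = min(P(X ≤ x), P(X ≥ x)), the p-value is the
    total probability of outcomes whose acceptability does not exceed that
    of the observed outcome (a small multiplicative slack absorbs
    floating-point ties).
    """
    support = dist.support
    if observed < support[0] or observed > support[-1]:
        raise ValueError(f"observed={observed} outside support [0, {support[-1]}]")
    pmf = dist.pmf
    cdf = np.cumsum(pmf)
    sf = np.cumsum(pmf[::-1])[::-1]  # P(X >= x)
    gamma = np.minimum(cdf, sf)
    g_obs = gamma[int(observed)]
    p = float(pmf[gamma <= g_obs * (1.0 + BLAKER_TIE_SLACK)].sum())
    return min(p, 1.0)


# ---------------------------------------------------------------------------
# fold enrichment, bootstrap intervals, the scan
# ---------------------------------------------------------------------------

@dataclass
class EnrichmentResult:
    """Fold-enrichment test of one additive combination in one food group."""

    combo: tuple[str, ...]
    group: str | None
    n_group: int
    sizes: tuple[int, ...]
    observed: int
    expected: float
    fold_enrichment: float
    p_two_sided: float
    ci_log_fe: tuple[float, float] | None = None
    n_degenerate_reps: int = 0
    B: int = 0
    seed: int | None = None
    q_bh: float | None = None

    def to_dict(self) -> dict:
        lo, hi = self.ci_log_fe if self.ci_log_fe is not None else (np.nan, np.nan)
        return {
            "combo": "&".join(self.combo),
            "group": self.group,
            "N": self.n_group,
            "sizes": "|".join(str(s) for s in self.sizes),
            "observed": self.observed,
            "expected": self.expected,
            "fold_enrichment": self.fold_enrichment,
            "p_two_sided": self.p_two_sided,
            "q_bh": self.q_bh,
            "ci_lo": lo,
            "ci_hi": hi,
            "n_degenerate_reps": self.n_degenerate_reps,
            "B": self.B,
            "seed": self.seed,
        }


def bootstrap_ci_logfe(
    columns: np.ndarray,
    B: int = 1000,
    seed: int | None = None,
    alpha: float = 0.05,
    batch: int = 200,
) -> tuple[tuple[float, float] | None, int]:
    """Percentile bootstrap interval for log fold enrichment of one combo.

    ``columns`` is the boolean n × m presence slab for the combination's
    codes.  Products (rows) are resampled with replacement; replicates with
    zero observed count or an empty marginal have undefined log FE and are
    excluded, their number reported alongside the interval.
    """
    if B < 100:
        raise ValueError("B must be at least 100")
    cols = np.asarray(columns, dtype=bool)
    n, m = cols.shape
    rng = np.random.default_rng(seed)
    row_all = cols.all(axis=1)
    logfes = np.empty(B)
    pos = 0
    for start in range(0, B, batch):
        b = min(batch, B - start)
        idx = rng.integers(0, n, size=(b, n))
        obs = row_all[idx].sum(axis=1).astype(float)
        sizes = np.stack([cols[:, j][idx].sum(axis=1) for j in range(m)], axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            expected = n * np.prod(sizes / n, axis=1)
            vals = np.log(obs) - np.log(expected)
        logfes[pos : pos + b] = vals
        pos += b
    defined = np.isfinite(logfes)
    n_degenerate = int((~defined).sum())
    if not defined.any():
        return None, n_degenerate
    lo, hi = np.percentile(logfes[defined], [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return (float(lo), float(hi)), n_degenerate


def enrichment_scan(
    matrix: PresenceMatrix,
    prevalence_min: float = 0.01,
    expected_min: float = 10.0,
    combo_sizes: tuple[int, ...] = (2, 3, 4),
    B: int = 1000,
    seed: int | None = None,
    min_group_size: int = 50,
    add_bh: bool = True,
) -> list[EnrichmentResult]:
    """Exhaustive fold-enrichment scan over additive combinations.

    Works on an already-lumped matrix restricted to one food group (or the
    whole market if the matrix has no group restriction).  Codes below
    ``prevalence_min`` within the group are dropped; combinations of the
    retained codes (at-least semantics: the product carries all codes of
    the combination, possibly others) are tested only when their expected
    count under independence reaches ``expected_min``.  ``B = 0`` skips the
    bootstrap.
    """
    N = matrix.n
    if N < min_group_size:
        warnings.warn(
            f"group {matrix.group!r} has {N} products (< {min_group_size}); skipped"
        )
        return []
    arr = matrix.data.values
    codes = matrix.codes
    col_sums = arr.sum(axis=0)
    keep = [j for j in range(len(codes)) if col_sums[j] / N >= prevalence_min]

    results: list[EnrichmentResult] = []
    rng_seed = np.random.default_rng(seed)
    for m in combo_sizes:
        for js in itertools.combinations(keep, m):
            sizes = tuple(int(col_sums[j]) for j in js)
            expected = N * float(np.prod([s / N for s in sizes]))
            if expected < expected_min:
                continue
            sub = arr[:, list(js)]
            observed = int(sub.all(axis=1).sum())
            dist = null_intersection_distribution(N, list(sizes))
            p = blaker_two_sided_p(dist, observed)
            fe = observed / expected
            ci, ndeg = (None, 0)
            combo_seed = None
            if B > 0:
                combo_seed = int(rng_seed.integers(0, 2**31 - 1))
                ci, ndeg = bootstrap_ci_logfe(sub, B=B, seed=combo_seed)
            results.append(
                EnrichmentResult(
                    combo=tuple(codes[j] for j in js),
                    group=matrix.group,
                    n_group=N,
                    sizes=sizes,
                    observed=observed,
                    expected=expected,
                    fold_enrichment=fe,
                    p_two_sided=p,
                    ci_log_fe=ci,
                    n_degenerate_reps=ndeg,
                    B=B,
                    seed=combo_seed,
                )
            )
    if add_bh and results:
        qs = multipletests([r.p_two_sided for r in results], method="fdr_bh")[1]
        for r, q in zip(results, qs):
            r.q_bh = float(q)
    return results


def enrichment_results_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame([r.to_dict() for r in results])


# ---------------------------------------------------------------------------
# nutrient correlations
# ---------------------------------------------------------------------------

def spearman_ets_nutrients(
    products: pd.DataFrame,
    nutrients: tuple[str, ...] = (
        "energy_kj",
        "fat_g",
        "satfat_g",
        "carb_g",
        "sugar_g",
        "protein_g",
        "sodium_g",
    ),
    cap: int = 10,
) -> pd.DataFrame:
    """Spearman rank correlation of capped additive count vs each nutrient.

    The additive count is capped at ``cap`` (the "10+" bin) before ranking;
    ties get average ranks (scipy's default).  Constant columns yield an
    undefined correlation, flagged rather than dropped.
    """
    counts = products["n_ets"].clip(upper=cap).to_numpy(dtype=float)
    rows = []
    for nut in nutrients:
        if nut not in products.columns:
            continue
        vals = pd.to_numeric(products[nut], errors="coerce").to_numpy(dtype=float)
        ok = np.isfinite(vals)
        x, y = counts[ok], vals[ok]
        if len(x) < 3 or np.all(y == y[0]) or np.all(x == x[0]):
            rows.append({"nutrient": nut, "rho": np.nan, "p": np.nan,
                         "n": int(len(x)), "defined": False})
            continue
        rho, p = sps.spearmanr(x, y)
        rows.append({"nutrient": nut, "rho": float(rho), "p": float(p),
                     "n": int(len(x)), "defined": True})
    return pd.DataFrame(rows)
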