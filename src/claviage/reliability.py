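"""Chance-corrected inter- and intra-rater agreement statistics.

Implements Cohen's kappa (two raters), Fleiss' kappa (three or more raters)
with and without linear ordinal weights, and Krippendorff's alpha with
nominal/ordinal/interval difference functions and missing ratings allowed.
Linear weights credit near-miss disagreements on the ordered staging scale:
``w[i, j] = 1 - |rank_i - rank_j| / (K - 1)`` over the category set in use.

The ``NE`` (not evaluable) marker can participate as an extra nominal
category in unweighted statistics; weighted variants are computed on the
subset where every rating is a real stage, mirroring how staging studies
report the two.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .staging import NOT_EVALUABLE, STAGES

Scheme = str  # fleiss_unweighted | fleiss_linear_weighted | cohen_unweighted | ...


@dataclass(frozen=True)
class AgreementResult:
    """A chance-corrected agreement estimate.

    estimate is dimensionless in [-1, 1]; 1 means perfect observed agreement
    (provided expected agreement < 1).  ``p_value`` is the two-sided
    large-sample normal test of no agreement beyond chance, where defined.
    """

    estimate: float
    scheme: Scheme
    n_items: int
    p_value: float | None = None


class DegenerateAgreement(ValueError):
    """Agreement undefined: expected agreement is 1 (no category variation)."""


def _category_order(values) -> list:
    """Order categories: stage codes by developmental rank (NE last), else sorted."""
    cats = set(values)
    stage_rankable = cats <= (set(STAGES) | {NOT_EVALUABLE})
    if stage_rankable:
        order = [s for s in STAGES if s in cats]
        if NOT_EVALUABLE in cats:
            order.append(NOT_EVALUABLE)
        return order
    return sorted(cats)


def _weight_matrix(k: int, weights: str) -> np.ndarray:
    if weights in (None, "none"):
        return np.eye(k)
    if weights == "linear":
        if k == 1:
            return np.eye(1)
        idx = np.arange(k)
        return 1.0 - np.abs(idx[:, None] - idx[None, :]) / (k - 1)
    raise ValueError(f"unknown weighting scheme {weights!r}")


# ---------------------------------------------------------------------------
# Cohen's kappa (two raters)


def cohen_kappa(
    r1,
    r2,
    weights: str = "none",
    categories: list | None = None,
    p_method: str = "normal",
    n_permutations: int = 2000,
    permutation_seed: int = 0,
) -> AgreementResult:
    """Cohen's kappa between two raters, optionally linearly weighted.

    kappa = (p_o - p_e) / (1 - p_e) with the weighted generalisation using
    w[i, j] over the category set; the p-value comes from the large-sample
    normal approximation with the Fleiss-Cohen-Everitt null variance, or —
    for small samples — from an exact-style Monte-Carlo permutation null
    (``p_method="permutation"``) that shuffles one rater's labels.
    """
    r1 = np.asarray(r1, dtype=object)
    r2 = np.asarray(r2, dtype=object)
    if r1.shape != r2.shape or r1.ndim != 1 or len(r1) < 2:
        raise ValueError("r1 and r2 must be equal-length vectors of length >= 2")
    if categories is None:
        categories = _category_order(np.concatenate([r1, r2]))
    k = len(categories)
    pos = {c: i for i, c in enumerate(categories)}
    n = len(r1)
    f = np.zeros((k, k))
    for a, b in zip(r1, r2):
        f[pos[a], pos[b]] += 1
    p = f / n
    w = _weight_matrix(k, weights)
    row = p.sum(axis=1)
    col = p.sum(axis=0)
    p_o = float((w * p).sum())
    p_e = float((w * np.outer(row, col)).sum())
    if p_e >= 1.0 - 1e-12:
        raise DegenerateAgreement("expected agreement is 1; kappa undefined")
    kappa = (p_o - p_e) / (1.0 - p_e)
    # Fleiss, Cohen & Everitt (1969) null variance for (weighted) kappa.
    wbar_row = w @ col  # E[w | rater-1 category i]
    wbar_col = row @ w  # E[w | rater-2 category j]
    term = (w - (wbar_row[:, None] + wbar_col[None, :])) ** 2
    var0 = (float((np.outer(row, col) * term).sum()) - p_e**2) / (n * (1.0 - p_e) ** 2)
    if p_method == "permutation":
        rng = np.random.default_rng(permutation_seed)
        idx1 = np.array([pos[a] for a in r1])
        idx2 = np.array([pos[b] for b in r2])
        hits = 0
        for _ in range(n_permutations):
            perm = rng.permutation(n)
            po_p = float(w[idx1, idx2[perm]].mean())
            hits += abs((po_p - p_e) / (1 - p_e)) >= abs(kappa) - 1e-12
        p_value = (hits + 1) / (n_permutations + 1)
    elif var0 > 0:
        z = kappa / np.sqrt(var0)
        p_value = float(2 * stats.norm.sf(abs(z)))
    else:
        p_value = None
    scheme = "cohen_linear_weighted" if weights == "linear" else "cohen_unweighted"
    return AgreementResult(float(kappa), scheme, n, p_value)


# ---------------------------------------------------------------------------
# Fleiss' kappa (>= 2 raters, complete data)


def _count_matrix(ratings: np.ndarray, categories: list) -> np.ndarray:
    """items x categories matrix of vote counts."""
    pos = {c: i for i, c in enumerate(categories)}
    counts = np.zeros((ratings.shape[0], len(categories)))
    for i, row in enumerate(ratings):
        for v in row:
            counts[i, pos[v]] += 1
    return counts


def fleiss_kappa(
    ratings,
    weights: str = "none",
    categories: list | None = None,
) -> AgreementResult:
    """Multi-rater kappa on an items x raters categorical matrix.

    Unweighted: the classic Fleiss statistic (observed vs chance mean
    pairwise agreement) with the Fleiss-Nee-Landis null variance for the
    p-value.  Weighted: the mean pairwise-weighted-agreement generalisation
    with linear weights; each pairwise sub-computation coincides with
    weighted Cohen agreement, and identity weights recover the unweighted
    statistic.  Items must be rated by every rater (pre-filter otherwise).
    """
    ratings = np.asarray(ratings, dtype=object)
    if ratings.ndim != 2 or ratings.shape[0] < 2 or ratings.shape[1] < 2:
        raise ValueError("need an items x raters matrix with >= 2 items and >= 2 raters")
    n_items, m = ratings.shape
    if categories is None:
        categories = _category_order(ratings.ravel())
    counts = _count_matrix(ratings, categories)
    w = _weight_matrix(len(categories), weights)
    p_cat = counts.sum(axis=0) / (n_items * m)
    # observed: mean weighted agreement over unordered rater pairs per item
    pair_w = np.einsum("ij,jk,ik->i", counts, w, counts) - counts @ np.diag(w).T
    p_obs = float((pair_w / (m * (m - 1))).mean())
    p_exp = float(p_cat @ w @ p_cat)
    if p_exp >= 1.0 - 1e-12:
        raise DegenerateAgreement("expected agreement is 1; kappa undefined")
    kappa = (p_obs - p_exp) / (1.0 - p_exp)
    p_value = None
    if weights in (None, "none"):
        # Fleiss-Nee-Landis large-sample null variance
        pe = float((p_cat**2).sum())
        num = pe - (2 * m - 3) * pe**2 + 2 * (m - 2) * float((p_cat**3).sum())
        var0 = 2.0 * num / (n_items * m * (m - 1) * (1.0 - pe) ** 2)
        if var0 > 0:
            z = kappa / np.sqrt(var0)
            p_value = float(2 * stats.norm.sf(abs(z)))
    scheme = "fleiss_linear_weighted" if weights == "linear" else "fleiss_unweighted"
    return AgreementResult(float(kappa), scheme, n_items, p_value)


# ---------------------------------------------------------------------------
# Krippendorff's alpha (missing allowed)


def krippendorff_alpha(
    ratings,
    metric: str = "ordinal",
    categories: list | None = None,
) -> float:
    """Krippendorff's alpha on an items x raters matrix with missing cells.

    alpha = 1 - D_o / D_e from the coincidence matrix; missing ratings
    (None or NaN) are simply absent from the coincidences, and items with a
    single rating contribute nothing.  ``metric`` selects the squared
    difference function: ``nominal``, ``ordinal`` (default, matching the
    ordered staging scale) or ``interval`` on category ranks.
    """
    ratings = np.asarray(ratings, dtype=object)

    def _missing(v) -> bool:
        return v is None or (isinstance(v, float) and np.isnan(v))

    items = [[v for v in row if not _missing(v)] for row in ratings]
    items = [row for row in items if len(row) >= 2]
    if not items:
        raise DegenerateAgreement("no item carries two or more ratings")
    if categories is None:
        categories = _category_order([v for row in items for v in row])
    k = len(categories)
    pos = {c: i for i, c in enumerate(categories)}
    o = np.zeros((k, k))
    for row in items:
        m_u = len(row)
        for a in range(m_u):
            for b in range(m_u):
                if a != b:
                    o[pos[row[a]], pos[row[b]]] += 1.0 / (m_u - 1)
    n_c = o.sum(axis=1)
    n = n_c.sum()
    if metric == "nominal":
        delta = 1.0 - np.eye(k)
    elif metric == "interval":
        idx = np.arange(k, dtype=float)
        delta = (idx[:, None] - idx[None, :]) ** 2
    elif metric == "ordinal":
        delta = np.zeros((k, k))
        for c in range(k):
            for d in range(k):
                lo, hi = min(c, d), max(c, d)
                s = n_c[lo : hi + 1].sum() - (n_c[c] + n_c[d]) / 2.0
                delta[c, d] = s**2
    else:
        raise ValueError(f"unknown metric {metric!r}")
    d_o = float((o * delta).sum())
    d_e = float(n_c @ delta @ n_c - (n_c * np.diag(delta)).sum()) / (n - 1)
    # diagonal of delta is zero for all three metrics, so d_e = n_c' delta n_c/(n-1)
    if d_e <= 0:
        raise DegenerateAgreement("expected disagreement is zero; alpha undefined")
    return 1.0 - d_o / d_e


# ---------------------------------------------------------------------------
# intra-rater agreement


def intra_rater(
    first_pass,
    second_pass,
    include_not_evaluable: bool = True,
) -> AgreementResult:
    """Agreement between one rater's two readings of the same items.

    With ``include_not_evaluable`` the unweighted kappa is computed over the
    stage categories plus ``NE``; without it, linearly weighted kappa on the
    subset where both passes assigned a real stage.
    """
    r1 = np.asarray(first_pass, dtype=object)
    r2 = np.asarray(second_pass, dtype=object)
    if r1.shape != r2.shape:
        raise ValueError("the two passes must cover the same items")
    if include_not_evaluable:
        return cohen_kappa(r1, r2, weights="none")
    keep = np.array([a != NOT_EVALUABLE and b != NOT_EVALUABLE for a, b in zip(r1, r2)])
    return cohen_kappa(r1[keep], r2[keep], weights="linear")


# ---------------------------------------------------------------------------
# study-level report


def agreement_report(ratings_wide) -> "pd.DataFrame":
    """Long-format agreement table over all rater pairs plus pooled statistics.

    ``ratings_wide`` is an items x raters DataFrame of stage codes/``NE``.
    Rows: unweighted Fleiss (all items, NE as a category), linearly weighted
    Fleiss (items staged by all raters), Krippendorff's ordinal alpha, and
    per-pair weighted Cohen's kappa on jointly staged items.
    """
    import pandas as pd

    raters = list(ratings_wide.columns)
    mat = ratings_wide.to_numpy(dtype=object)
    rows = []
    res = fleiss_kappa(mat, weights="none")
    rows.append(("fleiss_unweighted", "all", res.n_items, res.estimate, res.p_value))
    staged = np.array([all(v != NOT_EVALUABLE for v in row) for row in mat])
    if staged.sum() >= 2:
        res = fleiss_kappa(mat[staged], weights="linear")
        rows.append(("fleiss_linear_weighted", "all", res.n_items, res.estimate, res.p_value))
    alpha_mat = np.where(mat == NOT_EVALUABLE, None, mat)
    rows.append(
        ("krippendorff_ordinal", "all", int(staged.size), krippendorff_alpha(alpha_mat), None)
    )
    for i in range(len(raters)):
        for j in range(i + 1, len(raters)):
            a, b = mat[:, i], mat[:, j]
            keep = np.array(
                [x != NOT_EVALUABLE and y != NOT_EVALUABLE for x, y in zip(a, b)]
            )
            if keep.sum() < 2:
                continue
            res = cohen_kappa(a[keep], b[keep], weights="linear")
            rows.append(
                (
                    "cohen_linear_weighted",
                    f"{raters[i]}-{raters[j]}",
                    res.n_items,
                    res.estimate,
                    res.p_value,
                )
            )
    return pd.DataFrame(rows, columns=["scheme", "raters", "n", "estimate", "p_value"])
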