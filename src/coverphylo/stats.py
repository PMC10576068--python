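"""Community-structure and suppression statistics.

PERMANOVA partitions a dissimilarity matrix by design factors through the
Gower-centered inner-product matrix G = -1/2 J D^2 J (the distance-based
linear model): the sum of squares attributable to a model term is the trace
of its projection applied to G, terms are accumulated sequentially in the
stated order, and the pseudo-F of each term is referenced to a permutation
distribution obtained by relabeling plots.  Beta-dispersion (the
homogeneity check) embeds the plots by principal coordinates and compares
distances to group centroids.  Suppression summaries and one-sample /
block-paired t-tests cover the univariate side of the analysis; full mixed
models are deliberately out of scope here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "PermanovaResult",
    "DispersionResult",
    "GroupTestResult",
    "suppression_summary",
    "permanova",
    "beta_dispersion",
    "one_sample_test",
    "treatment_contrast",
    "holm_adjust",
]


# -- results ------------------------------------------------------------


@dataclass(frozen=True)
class PermanovaResult:
    """Sequential-SS PERMANOVA table with permutation p-values."""

    table: pd.DataFrame  # term, df, ss, pseudo_F, p_value
    total_ss: float
    n_perm: int
    seed: int

    def __post_init__(self):
        resid_ss = float(self.table.loc[self.table["term"] == "residual", "ss"].iloc[0])
        term_ss = float(
            self.table.loc[self.table["term"] != "residual", "ss"].sum()
        )
        if not np.isclose(term_ss + resid_ss, self.total_ss, atol=1e-9, rtol=1e-9):
            raise AssertionError("sums of squares do not add to the total")


@dataclass(frozen=True)
class DispersionResult:
    distances: pd.Series  # per-plot distance to its group centroid
    group_means: pd.Series
    f_statistic: float
    p_value: float
    n_perm: int
    seed: int


@dataclass(frozen=True)
class GroupTestResult:
    estimate: float
    t_statistic: float
    df: int
    p_value: float
    n: int


# -- suppression --------------------------------------------------------


def suppression_summary(table) -> pd.DataFrame:
    """Mean total weed biomass and percent suppression per site x treatment.

    Totals include unknown species (they are weeds with biomass).  Means
    pool site-years and blocks within a site.  Suppression is
    ``100 * (1 - treatment mean / control mean)``; negative suppression is
    reported as negative, never clipped.  A zero control mean flags the
    site's suppression undefined.
    """
    from coverphylo.community import CONTROL

    meta = table.plots()
    weedish = table.weed_like()
    totals = weedish.groupby("plot")["biomass"].sum().reindex(meta.index, fill_value=0.0)
    df = meta.assign(total_weed_biomass=totals)
    out = (
        df.groupby(["site", "treatment"], as_index=False)["total_weed_biomass"]
        .agg(mean_biomass="mean", n_plots="count")
    )
    control = out[out["treatment"] == CONTROL].set_index("site")["mean_biomass"]
    missing = sorted(set(out["site"]) - set(control.index))
    if missing:
        raise ValueError(f"no control treatment at site(s): {missing}")
    out["control_mean"] = out["site"].map(control)
    with np.errstate(divide="ignore", invalid="ignore"):
        out["suppression_pct"] = 100.0 * (1.0 - out["mean_biomass"] / out["control_mean"])
    out["defined"] = out["control_mean"] > 0
    out.loc[~out["defined"], "suppression_pct"] = np.nan
    out.loc[out["treatment"] == CONTROL, "suppression_pct"] = np.where(
        out.loc[out["treatment"] == CONTROL, "defined"], 0.0, np.nan
    )
    return out


# -- PERMANOVA ----------------------------------------------------------


def _term_dummies(design: pd.DataFrame, term: str) -> np.ndarray:
    """Indicator columns for a main effect or an 'a:b' interaction."""
    factors = term.split(":")
    for f in factors:
        if f not in design.columns:
            raise ValueError(f"term {term!r}: column {f!r} not in design")
        if design[f].nunique() < 2:
            raise ValueError(f"term {term!r}: factor {f!r} has a single level")
    combo = design[factors[0]].astype(str)
    for f in factors[1:]:
        combo = combo + ":" + design[f].astype(str)
    return pd.get_dummies(combo).to_numpy(dtype=float)


def _projection(X: np.ndarray) -> np.ndarray:
    """Orthogonal projector onto the column space of X."""
    Q, R = np.linalg.qr(X)
    keep = np.abs(np.diag(R)) > 1e-10 * max(1.0, np.abs(np.diag(R)).max())
    Q = Q[:, keep]
    return Q @ Q.T


def _gower(D: np.ndarray) -> np.ndarray:
    n = len(D)
    A = -0.5 * D**2
    J = np.eye(n) - np.ones((n, n)) / n
    return J @ A @ J


def permanova(
    D: pd.DataFrame,
    design: pd.DataFrame,
    terms: list[str] = ("site", "treatment", "site:treatment"),
    n_perm: int = 999,
    seed: int = 0,
    strata: str | None = None,
) -> PermanovaResult:
    """Permutational multivariate ANOVA on a dissimilarity matrix.

    ``D`` is a symmetric plot x plot dissimilarity matrix (pandas, labeled
    by plot id); ``design`` holds one metadata row per plot.  ``terms``
    are fitted sequentially in the given order; interactions use
    ``'a:b'``.  The permutation p-value uses the add-one rule
    ``p = (1 + #{F* >= F_obs}) / (1 + n_perm)``, with ties counted as
    exceedances.  ``strata`` restricts permutations to within the levels
    of one design column (e.g. within-site relabeling).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    design = design.loc[D.index]
    Dv = np.asarray(D, dtype=float)
    if not np.allclose(Dv, Dv.T):
        raise ValueError("dissimilarity matrix is not symmetric")
    if np.isnan(Dv).any():
        raise ValueError("dissimilarity matrix has missing entries")
    n = len(Dv)
    G = _gower(Dv)
    total_ss = float(np.trace(G))
    if total_ss <= 1e-12:
        raise ValueError("no multivariate variation: all plots are identical")

    terms = list(terms)
    ones = np.ones((n, 1))
    X = ones
    H_prev = _projection(X)
    rank_prev = 1
    projectors, dfs = [], []
    for term in terms:
        X = np.hstack([X, _term_dummies(design, term)])
        H = _projection(X)
        rank = int(round(np.trace(H)))
        df = rank - rank_prev
        if df < 1:
            raise ValueError(f"term {term!r} adds no degrees of freedom")
        projectors.append(H - H_prev)
        dfs.append(df)
        H_prev, rank_prev = H, rank
    resid_proj = np.eye(n) - H_prev
    df_resid = n - rank_prev
    if df_resid < 1:
        raise ValueError("saturated design: no residual degrees of freedom")

    ss_terms = np.array([float(np.sum(M * G)) for M in projectors])
    ss_resid = float(np.sum(resid_proj * G))
    ms_resid = ss_resid / df_resid
    f_obs = (ss_terms / np.array(dfs)) / ms_resid

    rng = np.random.default_rng(seed)
    perms = np.empty((n_perm, n), dtype=np.intp)
    base = np.arange(n)
    if strata is None:
        for k in range(n_perm):
            perms[k] = rng.permutation(n)
    else:
        groups = [
            np.flatnonzero(design[strata].to_numpy() == lev)
            for lev in pd.unique(design[strata])
        ]
        for k in range(n_perm):
            p = base.copy()
            for g in groups:
                p[g] = g[rng.permutation(len(g))]
            perms[k] = p

    exceed = np.zeros(len(terms))
    chunk = 200
    M_stack = np.stack(projectors)  # (T, n, n)
    for start in range(0, n_perm, chunk):
        pk = perms[start : start + chunk]
        Gp = G[pk[:, :, None], pk[:, None, :]]  # (P, n, n)
        ss_p = np.einsum("tij,pij->pt", M_stack, Gp)
        ss_res_p = total_ss - ss_p.sum(axis=1)
        f_p = (ss_p / np.array(dfs)) / (ss_res_p / df_resid)[:, None]
        exceed += (f_p >= f_obs - 1e-12).sum(axis=0)
    p_values = (1.0 + exceed) / (1.0 + n_perm)

    rows = [
        {"term": t, "df": d, "ss": s, "pseudo_F": f, "p_value": p}
        for t, d, s, f, p in zip(terms, dfs, ss_terms, f_obs, p_values)
    ]
    rows.append(
        {
            "term": "residual",
            "df": df_resid,
            "ss": ss_resid,
            "pseudo_F": np.nan,
            "p_value": np.nan,
        }
    )
    return PermanovaResult(
        table=pd.DataFrame(rows), total_ss=total_ss, n_perm=n_perm, seed=seed
    )


# -- beta dispersion -----------------------------------------------------


def _pcoa_coords(D: np.ndarray, tol: float = 1e-10):
    """Principal-coordinates axes, split into real and imaginary parts.

    Bray-Curtis matrices need not be Euclidean-embeddable; negative
    eigenvalues yield 'imaginary' axes whose squared contributions are
    subtracted from squared distances (the standard correction).
    """
    G = _gower(D)
    vals, vecs = np.linalg.eigh(G)
    scale = max(1.0, np.abs(vals).max())
    pos = vals > tol * scale
    neg = vals < -tol * scale
    X_pos = vecs[:, pos] * np.sqrt(vals[pos])
    X_neg = vecs[:, neg] * np.sqrt(-vals[neg])
    return X_pos, X_neg


def beta_dispersion(
    D: pd.DataFrame,
    groups: pd.Series,
    n_perm: int = 999,
    seed: int = 0,
) -> DispersionResult:
    """Homogeneity of multivariate dispersion around group centroids.

    Each plot's distance to its group centroid is measured in the
    principal-coordinates embedding of ``D``; the F statistic of a one-way
    ANOVA on these distances is referenced to a permutation distribution
    of the group labels.  A significant result means the groups differ in
    spread, cautioning the PERMANOVA location interpretation.
    """
    groups = groups.loc[D.index]
    labels = pd.unique(groups)
    if len(labels) < 2:
        raise ValueError("beta dispersion needs at least 2 groups")
    sizes = groups.value_counts()
    small = sizes[sizes < 2]
    if len(small):
        raise ValueError(
            f"group(s) with fewer than 2 members: {sorted(small.index)}"
        )
    Dv = np.asarray(D, dtype=float)
    X_pos, X_neg = _pcoa_coords(Dv)
    dist = np.empty(len(Dv))
    for lev in labels:
        idx = np.flatnonzero(groups.to_numpy() == lev)
        c_pos = X_pos[idx].mean(axis=0)
        c_neg = X_neg[idx].mean(axis=0) if X_neg.shape[1] else np.zeros(0)
        d2 = ((X_pos[idx] - c_pos) ** 2).sum(axis=1)
        if X_neg.shape[1]:
            d2 = d2 - ((X_neg[idx] - c_neg) ** 2).sum(axis=1)
        dist[idx] = np.sqrt(np.clip(d2, 0.0, None))

    g_codes = pd.Categorical(groups).codes
    f_obs = _anova_f(dist, g_codes, len(labels))
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        f_p = _anova_f(dist, rng.permutation(g_codes), len(labels))
        if f_p >= f_obs - 1e-12:
            exceed += 1
    p = (1.0 + exceed) / (1.0 + n_perm)
    dist_s = pd.Series(dist, index=D.index, name="dist_to_centroid")
    means = dist_s.groupby(groups).mean()
    return DispersionResult(
        distances=dist_s,
        group_means=means,
        f_statistic=float(f_obs),
        p_value=float(p),
        n_perm=n_perm,
        seed=seed,
    )


def _anova_f(y: np.ndarray, codes: np.ndarray, k: int) -> float:
    n = len(y)
    grand = y.mean()
    ssb = 0.0
    ssw = 0.0
    for g in range(k):
        yg = y[codes == g]
        m = yg.mean()
        ssb += len(yg) * (m - grand) ** 2
        ssw += ((yg - m) ** 2).sum()
    if ssw <= 0:
        return np.inf if ssb > 0 else 0.0
    return (ssb / (k - 1)) / (ssw / (n - k))


# -- univariate tests ----------------------------------------------------


def one_sample_test(values) -> GroupTestResult:
    """Two-sided one-sample t-test of mean = 0.

    Used on the per-pairing relativized MPD values: a significantly
    positive mean indicates weeds overdispersed relative to the cover
    crop, a negative mean phylogenetic clustering.
    """
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if len(v) < 2:
        raise ValueError(f"degenerate sample: n = {len(v)} (need >= 2)")
    if np.ptp(v) == 0:
        raise ValueError("degenerate sample: all values identical")
    res = sps.ttest_1samp(v, popmean=0.0)
    return GroupTestResult(
        estimate=float(v.mean()),
        t_statistic=float(res.statistic),
        df=len(v) - 1,
        p_value=float(res.pvalue),
        n=len(v),
    )


def treatment_contrast(
    mpd_table: pd.DataFrame,
    adjust: str | None = None,
) -> pd.DataFrame:
    """Block-paired treatment-vs-control contrasts on per-plot MPD.

    For each cover treatment, the within-block difference
    (treatment MPD - control MPD) is tested against zero with a paired
    (one-sample) t-test.  Pairs with an undefined MPD on either side are
    dropped and counted; a treatment with fewer than two complete pairs is
    flagged not testable.  ``adjust='holm'`` applies a Holm correction
    across treatments; p-values are raw by default.
    """
    from coverphylo.community import CONTROL

    df = mpd_table.copy()
    controls = df[df["treatment"] == CONTROL].set_index(["site", "year", "block"])
    rows = []
    for treatment, grp in df[df["treatment"] != CONTROL].groupby("treatment"):
        diffs, dropped = [], 0
        for r in grp.itertuples():
            key = (r.site, r.year, r.block)
            if key not in controls.index:
                dropped += 1
                continue
            ctl = controls.loc[key]
            if not (r.defined and bool(ctl["defined"])):
                dropped += 1
                continue
            diffs.append(r.mpd - float(ctl["mpd"]))
        diffs = np.asarray(diffs)
        if len(diffs) < 2:
            rows.append(
                {
                    "treatment": treatment,
                    "n_pairs": len(diffs),
                    "n_dropped": dropped,
                    "mean_diff": np.nan,
                    "t_statistic": np.nan,
                    "df": np.nan,
                    "p_value": np.nan,
                    "testable": False,
                }
            )
            continue
        if np.ptp(diffs) == 0:
            # identical differences carry no sampling variance; a zero
            # difference is the exact null, a nonzero one its extreme
            t = 0.0 if diffs[0] == 0 else np.inf * np.sign(diffs[0])
            p = 1.0 if diffs[0] == 0 else 0.0
            res = GroupTestResult(float(diffs.mean()), t, len(diffs) - 1, p, len(diffs))
        else:
            res = one_sample_test(diffs)
        rows.append(
            {
                "treatment": treatment,
                "n_pairs": res.n,
                "n_dropped": dropped,
                "mean_diff": res.estimate,
                "t_statistic": res.t_statistic,
                "df": res.df,
                "p_value": res.p_value,
                "testable": True,
            }
        )
    out = pd.DataFrame(rows)
    if adjust == "holm" and len(out):
        mask = out["testable"] & out["p_value"].notna()
        out.loc[mask, "p_adjusted"] = holm_adjust(out.loc[mask, "p_value"].to_numpy())
    return out


def holm_adjust(p: np.ndarray) -> np.ndarray:
    """Holm step-down adjustment of a vector of p-values."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj
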