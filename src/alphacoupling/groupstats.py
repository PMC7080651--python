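"""Group-level inference: mixed-design ANOVA, contrasts, correlations.

The mixed ANOVA is a classical balanced split-plot decomposition: one
between-subjects factor (group), any number of fully crossed within-subject
factors, subjects random.  Sums of squares are obtained by orthogonal
projections of the data tensor (group × subject × within-cells): each
within-effect subspace is the Kronecker product of centering projectors on
the factors in the effect and averaging projectors on the rest.  Error
strata follow the standard split-plot scheme — between effects are tested
against the subject-within-group mean square, each within effect (and its
interaction with group) against its own effect × subject stratum.

Greenhouse–Geisser epsilon is the Box epsilon of the pooled within-group
covariance of orthonormalized effect contrasts, ε = tr(S)² / (d·tr(S²)),
clipped to [1/d, 1]; for any 2-level within factor d = 1 and ε = 1 exactly,
so the corrected p equals the uncorrected one.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


def _helmert(n: int) -> np.ndarray:
    """(n−1) × n orthonormal contrast matrix with rows orthogonal to ones."""
    h = np.zeros((n - 1, n))
    for i in range(1, n):
        h[i - 1, :i] = 1.0
        h[i - 1, i] = -i
        h[i - 1] /= np.sqrt(i * (i + 1))
    return h


def mixed_anova(
    data: pd.DataFrame,
    dv: str,
    subject: str,
    between: str,
    within: list[str],
) -> pd.DataFrame:
    """Balanced mixed-design ANOVA.

    ``data`` is long format: one row per subject × within-cell with columns
    ``subject``, ``between`` (group label), one column per within factor and
    the dependent variable ``dv``.  Requires a complete within design for
    every subject and equal numbers of subjects per group.

    Returns a table with one row per effect: F, df_num, df_den,
    Greenhouse–Geisser ``eps``, uncorrected ``p_unc``, corrected ``p_gg``
    and ``partial_eta_sq``.
    """
    if not within:
        raise ValueError("need at least one within factor")
    groups = sorted(data[between].unique())
    G = len(groups)
    if G < 2:
        raise ValueError("need at least 2 groups")
    levels = {w: sorted(data[w].unique()) for w in within}
    shape_w = [len(levels[w]) for w in within]
    W = int(np.prod(shape_w))

    subj_by_group = {
        g: sorted(data.loc[data[between] == g, subject].unique()) for g in groups
    }
    ns = {g: len(s) for g, s in subj_by_group.items()}
    if len(set(ns.values())) != 1:
        raise ValueError(
            f"unequal group sizes {ns}: the balanced split-plot "
            "decomposition requires equal n per group"
        )
    n = next(iter(ns.values()))
    if n < 2:
        raise ValueError("need at least 2 subjects per group")

    # assemble data tensor Y: (G, n, L1, ..., Lm)
    idx = data.set_index([between, subject] + within)[dv]
    Y = np.empty((G, n) + tuple(shape_w))
    for gi, g in enumerate(groups):
        for si, s in enumerate(subj_by_group[g]):
            for combo in itertools.product(*(levels[w] for w in within)):
                key = (g, s) + combo
                if key not in idx.index:
                    raise ValueError(f"missing cell {key}")
                pos = tuple(levels[w].index(c) for w, c in zip(within, combo))
                Y[(gi, si) + pos] = float(idx.loc[key])

    m = len(within)
    waxes = tuple(range(2, 2 + m))

    def center(a: np.ndarray, axis: int) -> np.ndarray:
        return a - a.mean(axis=axis, keepdims=True)

    def project(a: np.ndarray, effect: tuple[int, ...]) -> np.ndarray:
        """Apply centering on within axes in `effect`, averaging on the rest."""
        out = a
        for ax in waxes:
            if ax in effect:
                out = center(out, ax)
            else:
                out = out.mean(axis=ax, keepdims=True)
        return out

    grand = Y.mean()
    subj_means = Y.mean(axis=waxes)  # (G, n)
    group_means = subj_means.mean(axis=1)  # (G,)

    rows = []
    # between-subjects stratum
    ss_between = W * n * float(np.sum((group_means - grand) ** 2))
    ss_subj = W * float(np.sum((subj_means - group_means[:, None]) ** 2))
    df_b, df_s = G - 1, G * (n - 1)
    if ss_subj <= 0:
        F_b = 0.0 if ss_between == 0 else np.inf
    else:
        F_b = (ss_between / df_b) / (ss_subj / df_s)
    p_b = float(stats.f.sf(F_b, df_b, df_s))
    rows.append(
        {
            "effect": between,
            "SS": ss_between,
            "SS_error": ss_subj,
            "df_num": df_b,
            "df_den": df_s,
            "F": F_b,
            "eps": 1.0,
            "p_unc": p_b,
            "p_gg": p_b,
            "partial_eta_sq": (
                ss_between / (ss_between + ss_subj)
                if (ss_between + ss_subj) > 0
                else 0.0
            ),
        }
    )

    # within-subject strata: one per nonempty subset of within factors
    for r in range(1, m + 1):
        for combo in itertools.combinations(range(m), r):
            effect_axes = tuple(waxes[i] for i in combo)
            df_e = int(np.prod([shape_w[i] - 1 for i in combo]))
            P = project(Y, effect_axes)  # still (G, n, ...) w/ kept axes
            cell = P.mean(axis=(0, 1), keepdims=True)
            grp = P.mean(axis=1, keepdims=True)
            scale = Y.size / P.size  # obs averaged into each kept cell
            ss_e = scale * float(np.sum(cell**2)) * (G * n)
            ss_eb = scale * float(np.sum((grp - cell) ** 2)) * n
            ss_err = scale * float(np.sum((P - grp) ** 2))
            df_eb = df_e * (G - 1)
            df_err = df_e * G * (n - 1)

            # GG epsilon from orthonormal effect contrasts
            C = np.ones((1, 1))
            for i in range(m):
                Li = shape_w[i]
                Ci = _helmert(Li) if i in combo else np.full((1, Li), 1.0 / np.sqrt(Li))
                C = np.kron(C, Ci)
            Z = Y.reshape(G, n, W) @ C.T  # (G, n, df_e)
            Zc = Z - Z.mean(axis=1, keepdims=True)
            S = np.einsum("gni,gnj->ij", Zc, Zc) / (G * (n - 1))
            tr = np.trace(S)
            tr2 = np.trace(S @ S)
            if tr2 <= 0:
                eps = 1.0
            else:
                eps = float(np.clip(tr**2 / (df_e * tr2), 1.0 / df_e, 1.0))

            name = " * ".join(within[i] for i in combo)
            for eff_name, ss, dfn in (
                (name, ss_e, df_e),
                (f"{name} * {between}", ss_eb, df_eb),
            ):
                if ss_err <= 0:
                    F = 0.0 if ss == 0 else np.inf
                else:
                    F = (ss / dfn) / (ss_err / df_err)
                p_unc = float(stats.f.sf(F, dfn, df_err))
                p_gg = float(stats.f.sf(F, eps * dfn, eps * df_err))
                rows.append(
                    {
                        "effect": eff_name,
                        "SS": ss,
                        "SS_error": ss_err,
                        "df_num": dfn,
                        "df_den": df_err,
                        "F": F,
                        "eps": eps,
                        "p_unc": p_unc,
                        "p_gg": p_gg,
                        "partial_eta_sq": ss / (ss + ss_err) if (ss + ss_err) > 0 else 0.0,
                    }
                )
    return pd.DataFrame(rows)


@dataclass
class Contrast:
    """One pairwise comparison: paired (equal-length, matched order) or
    independent samples."""

    name: str
    x: np.ndarray
    y: np.ndarray
    paired: bool = False


def _cohens_d_pooled(x: np.ndarray, y: np.ndarray) -> float:
    nx, ny = len(x), len(y)
    sp = np.sqrt(
        ((nx - 1) * np.var(x, ddof=1) + (ny - 1) * np.var(y, ddof=1))
        / (nx + ny - 2)
    )
    if sp == 0:
        raise ValueError("zero pooled variance")
    return float((np.mean(x) - np.mean(y)) / sp)


def independent_t_d(x: np.ndarray, y: np.ndarray) -> dict:
    """Two-sample pooled-variance t test with Cohen's d (pooled SD)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs at least 2 values")
    t, p = stats.ttest_ind(x, y, equal_var=True)
    return {
        "estimate": float(np.mean(x) - np.mean(y)),
        "t": float(t),
        "df": len(x) + len(y) - 2,
        "p": float(p),
        "p_bonferroni": float(p),
        "cohens_d": _cohens_d_pooled(x, y),
    }


def posthoc_pairwise(family: list[Contrast]) -> pd.DataFrame:
    """t tests for a family of contrasts with Bonferroni correction over the
    family (p_bonferroni = min(1, m·p))."""
    if not family:
        raise ValueError("empty contrast family")
    m = len(family)
    rows = []
    for c in family:
        x = np.asarray(c.x, dtype=float)
        y = np.asarray(c.y, dtype=float)
        if c.paired:
            if len(x) != len(y):
                raise ValueError(f"paired contrast {c.name!r} length mismatch")
            t, p = stats.ttest_rel(x, y)
            df = len(x) - 1
            d_sd = np.std(x - y, ddof=1)
            d = float(np.mean(x - y) / d_sd) if d_sd > 0 else np.nan
        else:
            t, p = stats.ttest_ind(x, y, equal_var=True)
            df = len(x) + len(y) - 2
            d = _cohens_d_pooled(x, y)
        rows.append(
            {
                "contrast": c.name,
                "estimate": float(np.mean(x) - np.mean(y)),
                "t": float(t),
                "df": df,
                "p": float(p),
                "p_bonferroni": float(min(1.0, m * p)),
                "cohens_d": d,
            }
        )
    return pd.DataFrame(rows)


def feature_neuropsych_corr(
    features: pd.DataFrame,
    scores: pd.DataFrame,
    group: str,
    feature_cols: list[str] | None = None,
    score_cols: list[str] | None = None,
) -> pd.DataFrame:
    """Per-group Pearson correlations between subject features and
    neuropsychological scores.

    Both frames are indexed by subject and carry a ``group`` column; only
    subjects of ``group`` enter (no cross-group pooling, which would
    confound group mean differences with within-group association).
    """
    f = features[features["group"] == group]
    s = scores[scores["group"] == group]
    common = f.index.intersection(s.index)
    if len(common) < 3:
        raise ValueError(f"need >= 3 subjects in group {group!r}")
    f = f.loc[common]
    s = s.loc[common]
    feature_cols = feature_cols or [
        c for c in f.columns if c != "group" and np.issubdtype(f[c].dtype, np.number)
    ]
    score_cols = score_cols or [
        c for c in s.columns if c != "group" and np.issubdtype(s[c].dtype, np.number)
    ]
    rows = []
    for fc in feature_cols:
        for sc in score_cols:
            r, p = stats.pearsonr(f[fc], s[sc])
            rows.append(
                {"group": group, "feature": fc, "test": sc,
                 "r": float(r), "p": float(p), "n": len(common)}
            )
    return pd.DataFrame(rows)
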