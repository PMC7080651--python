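"""Within-subject alpha–RT coupling statistics.

Two complementary single-subject summaries of how prestimulus alpha power
relates to response speed:

* a **median split** of each condition's included trials into fast and slow
  bins at the median RT, with the mean alpha power per bin and their
  difference (slow − fast);
* the **Spearman rank correlation** between single-trial alpha power and RT,
  mapped through the Fisher transform z = 0.5·ln((1 + r)/(1 − r)) so that
  per-subject coefficients can be averaged and compared across groups.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import CONDITIONS


def median_split(
    table: pd.DataFrame,
    condition: str | None = None,
    scope: str = "condition",
    min_trials: int = 4,
) -> pd.DataFrame:
    """Assign fast/slow speed bins at the median RT.

    By default (``scope='condition'``) the median is computed over the
    included trials of each condition separately; ``scope='global'`` uses
    one median over all included trials.  Trials with RT strictly below the
    median are *fast*; trials at or above it are *slow* (ties go to slow:
    "faster than the median" is read strictly).  Only included trials are
    binned.
    """
    if scope not in ("condition", "global"):
        raise ValueError("scope must be 'condition' or 'global'")
    out = table.copy()
    if "included" not in out:
        raise ValueError("run exclude_trials first")
    out["speed_bin"] = "unassigned"
    conds = [condition] if condition is not None else list(out["condition"].unique())
    if scope == "global":
        inc_all = out["included"]
        global_median = float(out.loc[inc_all, "rt"].median())
    for cond in conds:
        m = out["included"] & (out["condition"] == cond)
        n = int(m.sum())
        if n < min_trials:
            raise ValueError(
                f"only {n} included trials in condition {cond!r} (need >= {min_trials})"
            )
        rts = out.loc[m, "rt"]
        if rts.nunique() == 1:
            raise ValueError(
                f"all RTs identical in condition {cond!r}; median split degenerate"
            )
        med = global_median if scope == "global" else float(rts.median())
        out.loc[m & (out["rt"] < med), "speed_bin"] = "fast"
        out.loc[m & (out["rt"] >= med), "speed_bin"] = "slow"
    return out


def speed_bin_power(table: pd.DataFrame) -> pd.DataFrame:
    """Per condition: mean alpha power over fast and slow bins and their
    difference (slow − fast).  Returns one row per condition."""
    rows = []
    for cond in CONDITIONS:
        sub = table[(table["condition"] == cond) & (table["speed_bin"] != "unassigned")]
        if len(sub) == 0:
            continue
        fast = sub.loc[sub["speed_bin"] == "fast", "alpha_power"]
        slow = sub.loc[sub["speed_bin"] == "slow", "alpha_power"]
        if len(fast) == 0 or len(slow) == 0:
            raise ValueError(f"empty speed bin in condition {cond!r}")
        rows.append(
            {
                "condition": cond,
                "alpha_fast": float(fast.mean()),
                "alpha_slow": float(slow.mean()),
                "alpha_diff": float(slow.mean() - fast.mean()),
                "n_fast": len(fast),
                "n_slow": len(slow),
            }
        )
    return pd.DataFrame(rows)


def spearman_rho(alpha: np.ndarray, rt: np.ndarray) -> float:
    """Spearman rank correlation (average ranks for ties)."""
    alpha = np.asarray(alpha, dtype=float)
    rt = np.asarray(rt, dtype=float)
    if alpha.shape != rt.shape or alpha.ndim != 1:
        raise ValueError("alpha and rt must be equal-length 1-D vectors")
    if alpha.size < 4:
        raise ValueError("need at least 4 trials")
    if np.ptp(alpha) == 0 or np.ptp(rt) == 0:
        raise ValueError("zero variance in alpha or rt")
    rho = stats.spearmanr(alpha, rt).statistic
    return float(rho)


def fisher_z(rho: float, clamp: float | None = None) -> float:
    """Fisher transform z = 0.5·ln((1 + rho)/(1 − rho)).

    ``|rho| >= 1`` raises unless ``clamp`` is given, in which case rho is
    clamped to ±clamp first (for degenerate simulated subjects); clamping is
    never silent by default.
    """
    if not np.isfinite(rho):
        raise ValueError("rho must be finite")
    if abs(rho) >= 1.0:
        if clamp is None:
            raise ValueError(f"|rho| >= 1 (rho={rho}); pass clamp= to allow")
        rho = float(np.clip(rho, -clamp, clamp))
    return float(0.5 * np.log((1.0 + rho) / (1.0 - rho)))


def subject_coupling(
    table: pd.DataFrame,
    subject: str = "",
    group: str = "",
    clamp: float | None = 1.0 - 1e-7,
) -> pd.DataFrame:
    """Per-condition coupling summary for one subject.

    Expects ``alpha_power`` filled and speed bins assigned.  The Spearman
    correlation pools both speed bins (all included trials of the
    condition).  Returns a tidy frame: subject, group, condition, rho, z,
    alpha_fast, alpha_slow, alpha_diff, n_trials.
    """
    bins = speed_bin_power(table)
    rows = []
    for _, brow in bins.iterrows():
        cond = brow["condition"]
        sub = table[(table["condition"] == cond) & table["included"]]
        rho = spearman_rho(sub["alpha_power"].to_numpy(), sub["rt"].to_numpy())
        rows.append(
            {
                "subject": subject,
                "group": group,
                "condition": cond,
                "rho": rho,
                "z": fisher_z(rho, clamp=clamp),
                "alpha_fast": brow["alpha_fast"],
                "alpha_slow": brow["alpha_slow"],
                "alpha_diff": brow["alpha_diff"],
                "n_trials": int(len(sub)),
            }
        )
    return pd.DataFrame(rows)
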