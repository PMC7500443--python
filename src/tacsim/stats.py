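"""Repeated-measures inference from first principles.

Implements fully-within-subject ANOVA for arbitrary crossed designs via the
classical sums-of-squares decomposition (each effect tested against its own
effect-by-subject error stratum), the Greenhouse-Geisser sphericity
correction, Bonferroni adjustment, generalized eta squared (SS_effect over
SS_effect plus all subject-related SS), paired Cohen's d_z, marginal means
with t-based confidence intervals, and polynomial linear contrasts over
ordered factor levels.

The trial-level table is aggregated to one cell mean per subject and factor
combination before fitting; subjects with any empty cell are dropped
listwise with a warning.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "RmAnovaResult",
    "ContrastResult",
    "fit_rm_anova",
    "gg_epsilon",
    "bonferroni",
    "format_p",
    "marginal_means",
    "linear_contrast",
    "cohens_d",
]


@dataclass
class RmAnovaResult:
    """Per-effect ANOVA rows plus design metadata."""

    table: pd.DataFrame
    n_subjects: int
    factors: dict[str, list]
    dropped_subjects: list = field(default_factory=list)

    def effect(self, name: str) -> pd.Series:
        rows = self.table[self.table["effect"] == name]
        if rows.empty:
            raise KeyError(f"no effect named {name!r}")
        return rows.iloc[0]


@dataclass
class ContrastResult:
    estimate: float
    se: float
    t: float
    df: float
    p: float
    ci: tuple[float, float]
    degenerate: bool = False
    means: pd.DataFrame | None = None


def _cell_array(table: pd.DataFrame, dv: str, within: list[str],
                subject: str) -> tuple[np.ndarray, list, dict[str, list]]:
    """Aggregate to subject-by-cell means; listwise-drop incomplete subjects."""
    levels = {f: sorted(table[f].unique().tolist()) for f in within}
    agg = table.groupby([subject] + within, sort=True, observed=True)[dv].mean()
    subjects = sorted(table[subject].unique().tolist())
    shape = (len(subjects),) + tuple(len(levels[f]) for f in within)
    Y = np.full(shape, np.nan)
    idx = {f: {lv: i for i, lv in enumerate(levels[f])} for f in within}
    s_idx = {s: i for i, s in enumerate(subjects)}
    for key, val in agg.items():
        pos = (s_idx[key[0]],) + tuple(idx[f][k] for f, k in zip(within, key[1:]))
        Y[pos] = val
    flat = Y.reshape(len(subjects), -1)
    complete = ~np.isnan(flat).any(axis=1)
    dropped = [s for s, ok in zip(subjects, complete) if not ok]
    if dropped:
        warnings.warn(f"dropping subjects with empty cells: {dropped}")
    Y = Y[complete]
    if Y.shape[0] < 2:
        raise ValueError("need at least 2 complete subjects")
    kept = [s for s, ok in zip(subjects, complete) if ok]
    return Y, kept, levels


def _effect_ss(Y: np.ndarray, axes: tuple[int, ...]) -> float:
    """Sum of squares of one effect via inclusion-exclusion of marginal means."""
    eff = np.zeros((1,) * Y.ndim)
    for r in range(len(axes) + 1):
        for T in itertools.combinations(axes, r):
            collapse = tuple(a for a in range(Y.ndim) if a not in T)
            m = Y.mean(axis=collapse, keepdims=True)
            eff = eff + (-1.0) ** (len(axes) - len(T)) * m
    return float(np.sum(np.broadcast_to(eff, Y.shape) ** 2))


def _orthonormal_contrasts(k: int) -> np.ndarray:
    """(k, k-1) orthonormal sum-to-zero contrast matrix (Helmert-style)."""
    C = np.zeros((k, k - 1))
    for j in range(1, k):
        C[:j, j - 1] = 1.0
        C[j, j - 1] = -float(j)
        C[:, j - 1] /= np.linalg.norm(C[:, j - 1])
    return C


def _effect_epsilon(Y: np.ndarray, axes: tuple[int, ...],
                    k_sizes: tuple[int, ...]) -> float:
    """Greenhouse-Geisser epsilon of one within effect (contrast method)."""
    collapse = tuple(a for a in range(1, Y.ndim) if a not in axes)
    Z = Y.mean(axis=collapse) if collapse else Y
    Z = Z.reshape(Z.shape[0], -1)
    mats = [_orthonormal_contrasts(k) for k in k_sizes]
    C = mats[0]
    for m in mats[1:]:
        C = np.kron(C, m)
    sigma = np.cov(Z, rowvar=False, ddof=1)
    S = C.T @ sigma @ C
    df = C.shape[1]
    denom = df * float(np.trace(S @ S))
    if denom <= 0:
        return 1.0
    eps = float(np.trace(S)) ** 2 / denom
    return float(np.clip(eps, 1.0 / df, 1.0))


def fit_rm_anova(table: pd.DataFrame, dv: str, within: list[str],
                 subject: str = "subject") -> RmAnovaResult:
    """Fully-within repeated-measures ANOVA over the crossed ``within`` factors.

    Every effect (main and interaction) is tested against its own
    effect-by-subject stratum.  The Greenhouse-Geisser correction is applied
    to effects involving a factor with more than two levels; ``p_bonferroni``
    multiplies the (corrected) p by the number of effects in the model.
    """
    Y, kept, levels = _cell_array(table, dv, list(within), subject)
    for f, lv in levels.items():
        if len(lv) < 2:
            raise ValueError(f"factor {f!r} has fewer than 2 levels")
    n = Y.shape[0]
    factor_axes = {f: i + 1 for i, f in enumerate(within)}
    ss_subject = _effect_ss(Y, (0,))
    effects = []
    for r in range(1, len(within) + 1):
        effects.extend(itertools.combinations(within, r))

    # all subject-related SS for the generalized eta squared denominator
    ss_sub_strata = ss_subject + sum(
        _effect_ss(Y, tuple(factor_axes[f] for f in E) + (0,)) for E in effects)

    rows = []
    m = len(effects)
    for E in effects:
        axes = tuple(factor_axes[f] for f in E)
        ks = tuple(len(levels[f]) for f in E)
        df_num = int(np.prod([k - 1 for k in ks]))
        df_den = df_num * (n - 1)
        ss_eff = _effect_ss(Y, axes)
        ss_err = _effect_ss(Y, axes + (0,))
        if ss_eff <= 1e-300:
            F, p = 0.0, 1.0
        elif ss_err <= 1e-300:
            F, p = np.inf, 0.0
        else:
            F = (ss_eff / df_num) / (ss_err / df_den)
            p = float(sps.f.sf(F, df_num, df_den))
        eps = 1.0
        if max(ks) > 2:
            eps = _effect_epsilon(Y, axes, ks)
        df_num_c, df_den_c = eps * df_num, eps * df_den
        if eps < 1.0 and np.isfinite(F) and F > 0:
            p = float(sps.f.sf(F, df_num_c, df_den_c))
        eta = ss_eff / (ss_eff + ss_sub_strata) if ss_eff > 0 else 0.0
        rows.append({
            "effect": " x ".join(E),
            "df_num": df_num,
            "df_den": df_den,
            "epsilon": eps,
            "df_num_corr": df_num_c,
            "df_den_corr": df_den_c,
            "F": F,
            "p": p,
            "p_bonferroni": min(1.0, p * m),
            "eta_g2": eta,
        })
    return RmAnovaResult(table=pd.DataFrame(rows), n_subjects=n,
                         factors=levels,
                         dropped_subjects=[s for s in
                                           sorted(table[subject].unique())
                                           if s not in kept])


def gg_epsilon(cov: np.ndarray) -> float:
    """Box's epsilon-hat from the covariance of k repeated measures.

    Computed from the double-centered covariance; bounded to
    ``[1/(k-1), 1]``, equal to 1 under compound symmetry and always 1 for
    k = 2.
    """
    S = np.asarray(cov, dtype=float)
    if S.ndim != 2 or S.shape[0] != S.shape[1] or S.shape[0] < 2:
        raise ValueError("cov must be a k x k matrix with k >= 2")
    k = S.shape[0]
    H = np.eye(k) - np.ones((k, k)) / k
    Sc = H @ S @ H
    denom = (k - 1) * float(np.trace(Sc @ Sc))
    if denom <= 0:
        return 1.0
    eps = float(np.trace(Sc)) ** 2 / denom
    return float(np.clip(eps, 1.0 / (k - 1), 1.0))


def bonferroni(p_values, m: int):
    """Bonferroni adjustment ``min(1, p * m)``."""
    if m < 1:
        raise ValueError("m must be >= 1")
    out = np.minimum(1.0, np.asarray(p_values, dtype=float) * m)
    return float(out) if out.ndim == 0 else out


def format_p(p: float) -> str:
    """Display convention for adjusted p values: cap the print at '>0.999'."""
    if p > 0.999:
        return ">0.999"
    return f"{p:.4g}"


def marginal_means(table: pd.DataFrame, dv: str, factor: str,
                   subject: str = "subject", level=None,
                   confidence: float = 0.95):
    """Marginal means of subject-cell means per level of ``factor``.

    Returns a frame (level, mean, se, df, ci_low, ci_high) or, when *level*
    is given, a :class:`ContrastResult` for that level.  The CI uses the
    across-subject variability of the per-subject level means with
    ``df = n - 1``.
    """
    cell = table.groupby([subject, factor], observed=True)[dv].mean().unstack(factor)
    if cell.isna().any().any():
        raise ValueError("missing subject x level cells")
    n = cell.shape[0]
    means = cell.mean(axis=0)
    se = cell.std(axis=0, ddof=1) / np.sqrt(n)
    df = n - 1
    tcrit = sps.t.ppf(0.5 + confidence / 2.0, df)
    out = pd.DataFrame({
        "level": means.index,
        "mean": means.to_numpy(),
        "se": se.to_numpy(),
        "df": df,
        "ci_low": (means - tcrit * se).to_numpy(),
        "ci_high": (means + tcrit * se).to_numpy(),
    }).reset_index(drop=True)
    if level is None:
        return out
    row = out[out["level"] == level]
    if row.empty:
        raise ValueError(f"unknown level {level!r} of factor {factor!r}")
    r = row.iloc[0]
    t = r["mean"] / r["se"] if r["se"] > 0 else np.inf * np.sign(r["mean"])
    p = float(2 * sps.t.sf(abs(t), df)) if np.isfinite(t) else 0.0
    return ContrastResult(estimate=float(r["mean"]), se=float(r["se"]), t=float(t),
                          df=df, p=p, ci=(float(r["ci_low"]), float(r["ci_high"])),
                          means=out)


def linear_contrast(cell_means: np.ndarray, error_model: str = "subject",
                    confidence: float = 0.95) -> ContrastResult:
    """Linear polynomial contrast across k ordered levels (subjects x k input).

    Weights are the centered level indices normalized to unit norm (e.g.
    proportional to -3,-1,1,3 for k = 4).  ``error_model="subject"`` tests
    the per-subject contrast scores with a one-sample t (df = n-1);
    ``"pooled"`` uses the level-by-subject interaction stratum
    (df = (n-1)(k-1)).  A zero-variance error is reported as a degenerate
    infinite-t result, not an error.
    """
    Y = np.asarray(cell_means, dtype=float)
    if Y.ndim != 2:
        raise ValueError("cell_means must be (subjects, levels)")
    n, k = Y.shape
    if k < 3:
        raise ValueError("linear contrast needs at least 3 levels")
    w = np.arange(k, dtype=float)
    w -= w.mean()
    w /= np.linalg.norm(w)
    scores = Y @ w
    estimate = float(scores.mean())

    if error_model == "subject":
        sd = float(scores.std(ddof=1))
        se = sd / np.sqrt(n)
        df = n - 1
    elif error_model == "pooled":
        resid = Y - Y.mean(axis=1, keepdims=True) - Y.mean(axis=0) + Y.mean()
        ms = float(np.sum(resid**2)) / ((n - 1) * (k - 1))
        se = np.sqrt(ms / n)  # sum(w^2) == 1
        df = (n - 1) * (k - 1)
    else:
        raise ValueError(f"unknown error_model {error_model!r}")

    if se == 0:
        sign = np.sign(estimate) if estimate != 0 else 1.0
        return ContrastResult(estimate=estimate, se=0.0, t=sign * np.inf, df=df,
                              p=0.0 if estimate != 0 else 1.0,
                              ci=(estimate, estimate), degenerate=True)
    t = estimate / se
    p = float(2 * sps.t.sf(abs(t), df))
    tcrit = sps.t.ppf(0.5 + confidence / 2.0, df)
    return ContrastResult(estimate=estimate, se=se, t=float(t), df=df, p=p,
                          ci=(estimate - tcrit * se, estimate + tcrit * se))


def cohens_d(paired_a, paired_b) -> float:
    """Paired-design effect size d_z = mean(a - b) / sd(a - b)."""
    a = np.asarray(paired_a, dtype=float)
    b = np.asarray(paired_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("need equal-length 1-D samples with n >= 2")
    d = a - b
    sd = d.std(ddof=1)
    if sd == 0:
        if np.all(d == 0):
            return 0.0  # identical samples: no effect by convention
        raise ValueError("zero standard deviation of differences")
    return float(d.mean() / sd)
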