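"""Common spatial patterns contrasting pre- vs post-stimulation covariance.

Filters solve the generalized eigenproblem ``C_pre w = lambda (C_pre +
C_post) w`` (eigenvalues in [0, 1]; numerically stabler than the ratio form
and identical ordering).  The first filter maximizes pre/post power
("CSPpre"), the last maximizes post/pre ("CSPpost").  Per-trial components
come from a leave-one-trial-out regime: the filter applied to trial i is fit
on the mean covariances of all other trials.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg

from .montage import ChannelLayout
from .power import TrialEpochs, window_alpha_power

__all__ = [
    "CovariancePair",
    "SpatialFilters",
    "LotoComponents",
    "trial_covariance",
    "shrink",
    "csp_fit",
    "loto_components",
    "component_alpha_power",
    "average_pattern",
]


@dataclass
class CovariancePair:
    """Averaged pre/post covariance matrices entering the CSP objective."""

    C_pre: np.ndarray
    C_post: np.ndarray
    n_trials_used: int

    def __post_init__(self) -> None:
        for C in (self.C_pre, self.C_post):
            if C.shape != self.C_pre.shape or C.ndim != 2 or \
                    C.shape[0] != C.shape[1]:
                raise ValueError("covariances must be square and same-shaped")
            if not np.allclose(C, C.T, atol=1e-10):
                raise ValueError("covariance not symmetric")

    @classmethod
    def from_epochs(cls, pre_epochs: "TrialEpochs",
                    post_epochs: "TrialEpochs") -> "CovariancePair":
        """Mean trace-normalized trial covariances of all trials."""
        n = pre_epochs.n_trials
        if post_epochs.n_trials != n:
            raise ValueError("pre/post trial counts differ")
        C_pre = np.mean([trial_covariance(pre_epochs.data[i])
                         for i in range(n)], axis=0)
        C_post = np.mean([trial_covariance(post_epochs.data[i])
                          for i in range(n)], axis=0)
        return cls(C_pre=C_pre, C_post=C_post, n_trials_used=n)


@dataclass
class SpatialFilters:
    """CSP filters (rows of ``W``), eigenvalues and activation patterns."""

    W: np.ndarray  # (n_filters, n_channels)
    eigenvalues: np.ndarray  # descending, in [0, 1]
    patterns: np.ndarray  # (n_channels, n_filters)
    orientation: str = "pre-max"

    @property
    def csp_pre(self) -> np.ndarray:
        return self.W[0]

    @property
    def csp_post(self) -> np.ndarray:
        return self.W[-1]


@dataclass
class LotoComponents:
    """Leave-one-trial-out component series and per-fold filters."""

    components: dict[str, dict[str, np.ndarray]]  # source -> window -> (trials, samples)
    filters: dict[str, np.ndarray]  # source -> (trials, channels)
    patterns: dict[str, np.ndarray]  # source -> (channels,) mean fold pattern


def _raw_covariance(epoch: np.ndarray) -> np.ndarray:
    X = np.asarray(epoch, dtype=float)
    if X.ndim != 2:
        raise ValueError("epoch must be (channels, samples)")
    return X @ X.T / X.shape[1]


def trial_covariance(epoch: np.ndarray) -> np.ndarray:
    """Trace-normalized sample covariance ``X X^T / n`` of one epoch."""
    X = np.asarray(epoch, dtype=float)
    if X.ndim != 2:
        raise ValueError("epoch must be (channels, samples)")
    C = X @ X.T / X.shape[1]
    tr = np.trace(C)
    if tr <= 0:
        raise ValueError("zero-variance epoch")
    return C / tr


def shrink(C: np.ndarray, gamma: float = 1e-6) -> np.ndarray:
    """Shrinkage toward the scaled identity to guarantee positive definiteness."""
    d = C.shape[0]
    return (1.0 - gamma) * C + gamma * (np.trace(C) / d) * np.eye(d)


def csp_fit(C_pre: np.ndarray, C_post: np.ndarray,
            gamma: float = 1e-6) -> SpatialFilters:
    """Fit CSP filters from a pre/post covariance pair.

    Eigenvectors are normalized to ``w^T (C_pre + C_post) w = 1`` and sorted
    by eigenvalue descending, so row 0 maximizes the pre/post power ratio and
    the last row the post/pre ratio.
    """
    C_pre = shrink(np.asarray(C_pre, dtype=float), gamma)
    C_post = shrink(np.asarray(C_post, dtype=float), gamma)
    comp = C_pre + C_post
    try:
        evals, evecs = linalg.eigh(C_pre, comp, check_finite=False)
    except linalg.LinAlgError as exc:
        raise ValueError(f"composite covariance not positive definite: {exc}")
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    W = evecs[:, order].T  # rows are filters
    # A = comp @ W^T @ (W comp W^T)^-1; with eigh normalization this is comp @ W^T
    patterns = comp @ W.T @ np.linalg.inv(W @ comp @ W.T)
    return SpatialFilters(W=W, eigenvalues=evals, patterns=patterns)


def _align_signs(filters: np.ndarray, patterns: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Flip per-fold filter/pattern signs to agree with the mean across folds."""
    ref = filters[0]
    flip = np.where(filters @ ref < 0, -1.0, 1.0)
    mean = (filters * flip[:, None]).mean(axis=0)
    flip = np.where(filters @ mean < 0, -1.0, 1.0)
    return filters * flip[:, None], patterns * flip[:, None]


def loto_components(pre_epochs: TrialEpochs, post_epochs: TrialEpochs,
                    extra_windows: dict[str, TrialEpochs] | None = None,
                    gamma: float = 1e-6) -> LotoComponents:
    """Leave-one-trial-out CSP component series.

    For every trial i, filters are fit on the mean pre/post covariances of
    all trials except i, and trial i's windows (pre, post, and any
    ``extra_windows``) are projected through the held-out CSPpre and CSPpost
    filters.  Per-trial filter signs are aligned to the mean filter across
    folds so components are comparable between trials.
    """
    n = pre_epochs.n_trials
    if post_epochs.n_trials != n:
        raise ValueError("pre/post trial counts differ")
    if n < 3:
        raise ValueError("leave-one-trial-out needs at least 3 trials")
    # pre/post covariances are scaled by a COMMON per-trial normalizer:
    # normalizing each window separately would cancel exactly the global
    # pre-vs-post power change the filters are meant to contrast
    covs_pre, covs_post = [], []
    for i in range(n):
        Cp = _raw_covariance(pre_epochs.data[i])
        Cq = _raw_covariance(post_epochs.data[i])
        scale = (np.trace(Cp) + np.trace(Cq)) / 2.0
        if scale <= 0:
            raise ValueError(f"trial {i}: zero-variance epoch")
        covs_pre.append(Cp / scale)
        covs_post.append(Cq / scale)
    covs_pre = np.stack(covs_pre)
    covs_post = np.stack(covs_post)

    windows = {"pre": pre_epochs, "post": post_epochs}
    if extra_windows:
        windows.update(extra_windows)

    fold_w = {"CSPpre": [], "CSPpost": []}
    fold_a = {"CSPpre": [], "CSPpost": []}
    idx = np.arange(n)
    for i in range(n):
        mask = idx != i
        C_pre = np.mean(covs_pre[mask], axis=0)
        C_post = np.mean(covs_post[mask], axis=0)
        filt = csp_fit(C_pre, C_post, gamma=gamma)
        fold_w["CSPpre"].append(filt.csp_pre)
        fold_w["CSPpost"].append(filt.csp_post)
        fold_a["CSPpre"].append(filt.patterns[:, 0])
        fold_a["CSPpost"].append(filt.patterns[:, -1])

    components: dict[str, dict[str, np.ndarray]] = {}
    filters: dict[str, np.ndarray] = {}
    mean_patterns: dict[str, np.ndarray] = {}
    for source in ("CSPpre", "CSPpost"):
        w_aligned, a_aligned = _align_signs(np.array(fold_w[source]),
                                            np.array(fold_a[source]))
        filters[source] = w_aligned
        mean_patterns[source] = a_aligned.mean(axis=0)
        components[source] = {
            name: np.stack([w_aligned[i] @ ep.data[i] for i in range(n)])
            for name, ep in windows.items()
        }
    return LotoComponents(components=components, filters=filters,
                          patterns=mean_patterns)


def component_alpha_power(loto: LotoComponents, events: pd.DataFrame,
                          iaf: float, srate: float, subject: int = 0,
                          nfft: int = 512) -> pd.DataFrame:
    """Alpha power of the CSP component series, long-format table rows."""
    frames = []
    n = len(events)
    for source, by_window in loto.components.items():
        for window, series in by_window.items():
            p = window_alpha_power(series, iaf, srate, nfft)
            frames.append(pd.DataFrame({
                "subject": subject,
                "block": events["block"].to_numpy(),
                "trial": events["trial_id"].to_numpy(),
                "state": events["state"].to_numpy(),
                "stimulation": events["stimulation"].to_numpy(),
                "window": window,
                "source": source,
                "alpha_power": p[:n],
            }))
    return pd.concat(frames, ignore_index=True)


def average_pattern(patterns, layout: ChannelLayout) -> pd.DataFrame:
    """Sign-aligned grand-average activation pattern with channel positions.

    Each subject's pattern is flipped to correlate positively with the grand
    mean (one realignment iteration, seeded by the first subject).
    """
    P = np.array([np.asarray(p, dtype=float) for p in patterns])
    if P.ndim != 2 or P.shape[1] != len(layout):
        raise ValueError("patterns must be (n_subjects, n_channels)")
    flip = np.where(P @ P[0] < 0, -1.0, 1.0)
    g = (P * flip[:, None]).mean(axis=0)
    flip = np.where(P @ g < 0, -1.0, 1.0)
    g = (P * flip[:, None]).mean(axis=0)
    return pd.DataFrame({
        "channel": layout.labels,
        "x": layout.positions[:, 0],
        "y": layout.positions[:, 1],
        "weight": g,
    })
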