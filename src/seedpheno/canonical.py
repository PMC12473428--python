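"""Canonical variate (discriminant) analysis of the recovered groups.

Given genotype trait profiles and a hard group assignment, the
canonical axes are the eigenvectors of W^-1 B, where W and B are the
within-group and between-group scatter matrices of the standardized
traits. Axis i's eigenvalue measures the between-group separation it
carries; eigenvalue proportions say how much of the total separation
the first axes explain. Coefficients are standardized (traits enter as
z-scores) and scaled to unit pooled within-group variance, so a
trait's absolute coefficient on axis 1 is directly comparable across
traits; the conventional "contribution" of a trait to divergence is
100 * |axis-1 coefficient|.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg


@dataclass
class CanonicalResult:
    eigenvalues: np.ndarray
    proportions: np.ndarray
    cumulative: np.ndarray
    coefficients: pd.DataFrame  # trait x axis, standardized
    scores: pd.DataFrame  # observation x axis
    group_means: pd.DataFrame  # group x axis
    contributions: pd.Series  # percent, axis 1

    @property
    def n_axes(self) -> int:
        return len(self.eigenvalues)


def canonical_analysis(
    profiles: pd.DataFrame,
    groups: pd.Series,
    *,
    ridge: float = 1e-8,
) -> CanonicalResult:
    """Canonical discriminant analysis of grouped genotype profiles.

    At most min(n_traits, k-1) axes carry between-group variance; the
    returned axes are ordered by decreasing eigenvalue, and each axis's
    sign is fixed so its largest-|coefficient| trait loads positively.
    """
    groups = groups.reindex(profiles.index)
    if groups.isna().any():
        raise ValueError("every genotype needs a group assignment")
    levels = sorted(groups.unique())
    k = len(levels)
    if k < 2:
        raise ValueError("canonical analysis needs at least 2 groups")
    x = profiles.to_numpy(float)
    n, t = x.shape
    sd = x.std(axis=0, ddof=1)
    if np.any(sd == 0):
        const = list(profiles.columns[sd == 0])
        raise ValueError(f"traits with zero variance cannot be standardized: {const}")
    z = (x - x.mean(axis=0)) / sd

    w = np.zeros((t, t))
    b = np.zeros((t, t))
    grand = z.mean(axis=0)
    for lev in levels:
        sub = z[(groups == lev).to_numpy()]
        mu = sub.mean(axis=0)
        dev = sub - mu
        w += dev.T @ dev
        b += len(sub) * np.outer(mu - grand, mu - grand)
    w_r = w + ridge * (np.trace(w) / t if np.trace(w) > 0 else 1.0) * np.eye(t)
    try:
        evals, evecs = linalg.eigh(b, w_r)
    except linalg.LinAlgError as exc:
        raise linalg.LinAlgError("within-group scatter is singular after ridge") from exc

    order = np.argsort(evals)[::-1]
    n_axes = min(t, k - 1)
    evals = np.clip(evals[order][:n_axes], 0.0, None)
    vecs = evecs[:, order][:, :n_axes]

    # scale axes to unit pooled within-group variance: a' (W/(n-k)) a = 1
    within_var = np.einsum("ti,ts,si->i", vecs, w_r / (n - k), vecs)
    vecs = vecs / np.sqrt(within_var)
    # sign convention: dominant trait loads positively on each axis
    for i in range(n_axes):
        j = int(np.argmax(np.abs(vecs[:, i])))
        if vecs[j, i] < 0:
            vecs[:, i] *= -1.0

    total = evals.sum()
    proportions = evals / total if total > 0 else np.zeros_like(evals)
    axes = [f"CAN{i + 1}" for i in range(n_axes)]
    coefficients = pd.DataFrame(vecs, index=profiles.columns, columns=axes)
    scores = pd.DataFrame((z - grand) @ vecs, index=profiles.index, columns=axes)
    gmeans = scores.groupby(groups).mean()
    gmeans.index.name = "group"
    contributions = (100.0 * coefficients["CAN1"].abs()).rename("contribution_pct")
    return CanonicalResult(
        eigenvalues=evals,
        proportions=proportions,
        cumulative=np.cumsum(proportions),
        coefficients=coefficients,
        scores=scores,
        group_means=gmeans,
        contributions=contributions,
    )
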