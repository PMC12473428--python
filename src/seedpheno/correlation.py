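"""Pearson correlation of trait pairs with magnitude classification.

Correlations are computed on genotype means by default (one value per
genotype, the level at which clonal trials report trait association);
replicate-level ("phenotypic") correlation is available by passing the
replicate-level table's pivot instead. Significance uses the exact t
transform t = r * sqrt((n-2) / (1-r^2)) on n-2 degrees of freedom, at
alpha = 0.01 by default.

Magnitude classes follow the conventional breeding scale:
null (|r| = 0), weak (0 < |r| < 0.30), moderate (0.30 <= |r| < 0.60),
strong (0.60 <= |r| < 0.90), very strong (0.90 <= |r| < 1) and perfect
(|r| = 1). Boundary values are assigned to the upper class.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

MAGNITUDE_CLASSES = ("null", "weak", "moderate", "strong", "very strong", "perfect")


def classify_magnitude(r: float) -> str:
    """Total, deterministic class label for one correlation value."""
    if not np.isfinite(r):
        raise ValueError(f"correlation must be finite, got {r!r}")
    a = abs(float(r))
    if a > 1.0 + 1e-9:
        raise ValueError(f"|r| must be <= 1, got {r!r}")
    if a == 0.0:
        return "null"
    if a >= 1.0 - 1e-12:
        return "perfect"
    if a < 0.30:
        return "weak"
    if a < 0.60:
        return "moderate"
    if a < 0.90:
        return "strong"
    return "very strong"


@dataclass
class CorrelationResult:
    traits: list[str]
    r: pd.DataFrame
    t: pd.DataFrame
    p: pd.DataFrame
    significant: pd.DataFrame
    classes: pd.DataFrame
    counts: dict[str, int]
    percentages: dict[str, float]
    n: int
    alpha: float

    @property
    def n_pairs(self) -> int:
        t = len(self.traits)
        return t * (t - 1) // 2

    def pair_table(self) -> pd.DataFrame:
        """One row per unordered trait pair."""
        rows = []
        for i, a in enumerate(self.traits):
            for b in self.traits[i + 1 :]:
                rows.append(
                    {
                        "trait_a": a,
                        "trait_b": b,
                        "r": self.r.loc[a, b],
                        "t": self.t.loc[a, b],
                        "p": self.p.loc[a, b],
                        "significant": bool(self.significant.loc[a, b]),
                        "magnitude": self.classes.loc[a, b],
                    }
                )
        return pd.DataFrame(rows)


def _truncate2(x: float) -> float:
    return math.floor(x * 100.0) / 100.0


def correlation_matrix(profiles: pd.DataFrame, alpha: float = 0.01) -> CorrelationResult:
    """Pairwise Pearson correlation over trait columns.

    Per-class pair counts and their percentages of the C(t, 2) total
    are reported alongside; percentages are truncated (not rounded) to
    two decimals, the convention of the field's summary tables.
    """
    n = len(profiles)
    if n < 3:
        raise ValueError(f"need at least 3 genotypes, got {n}")
    sd = profiles.std(ddof=1)
    if (sd == 0).any():
        dropped = list(profiles.columns[(sd == 0).to_numpy()])
        warnings.warn(f"dropping zero-variance traits: {dropped}", stacklevel=2)
        profiles = profiles.loc[:, sd > 0]
    traits = list(profiles.columns)
    if len(traits) < 2:
        raise ValueError("need at least 2 traits with positive variance")
    r = profiles.corr(method="pearson")
    rv = r.to_numpy(float).copy()
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = rv * np.sqrt((n - 2) / np.clip(1.0 - rv**2, 0.0, None))
    pval = 2.0 * stats.t.sf(np.abs(tstat), df=n - 2)
    pval[np.isinf(tstat)] = 0.0
    np.fill_diagonal(tstat, np.inf)
    np.fill_diagonal(pval, 0.0)
    tdf = pd.DataFrame(tstat, index=traits, columns=traits)
    pdf = pd.DataFrame(pval, index=traits, columns=traits)
    sig = pdf < alpha
    classes = r.map(classify_magnitude)

    counts = dict.fromkeys(MAGNITUDE_CLASSES, 0)
    iu = np.triu_indices(len(traits), 1)
    for i, j in zip(*iu):
        counts[classes.iat[i, j]] += 1
    total = len(iu[0])
    percentages = {c: _truncate2(100.0 * counts[c] / total) for c in MAGNITUDE_CLASSES}
    return CorrelationResult(
        traits=traits,
        r=r,
        t=tdf,
        p=pdf,
        significant=sig,
        classes=classes,
        counts=counts,
        percentages=percentages,
        n=n,
        alpha=alpha,
    )
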