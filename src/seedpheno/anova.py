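"""RCBD analysis of variance and genetic-parameter estimation.

Model per trait: ``Y_ij = mu + G_i + B_j + E_ij`` — a randomized
complete block design in which every genotype appears once per block.
The classical two-way (genotype + block, no interaction) decomposition
gives mean squares MSG (genotypes), MSB (blocks) and MSE (residual),
from which the genetic parameters at the genotype-mean level follow:

* genotypic variance       sigma2_g = (MSG - MSE) / r
* phenotypic variance      sigma2_p = MSG / r
* environmental variance   sigma2_e = MSE / r
* broad-sense heritability h2 = sigma2_g / sigma2_p
* variation index          VI = CVg / CVe

``CVg = 100 * sqrt(sigma2_g) / mean``. For CVe two conventions exist:
plot level (``100 * sqrt(MSE) / mean``, the CV% printed in ANOVA
tables) and genotype-mean level (``100 * sqrt(MSE / r) / mean``). The
default is plot level, so VI = sqrt((MSG - MSE) / r) / sqrt(MSE); the
mean-level convention is available via ``cve_level="mean"``. VI > 1
signals that genotypic variation dominates the environmental noise,
i.e. favorable conditions for direct phenotypic selection.

Heritability here is heritability of genotype means (broad sense, clone
level); no additive/dominance partition is attempted.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from seedpheno.io import PhenotypeTable


@dataclass
class AnovaRow:
    """Per-trait ANOVA summary for a balanced g x r RCBD layout."""

    trait_id: str
    g: int
    r: int
    df_blocks: int
    df_genotypes: int
    df_residual: int
    df_total: int
    ms_blocks: float
    ms_genotypes: float
    ms_residual: float
    f_genotypes: float
    p_genotypes: float
    cv_pct: float
    grand_mean: float


@dataclass
class GeneticParameters:
    trait_id: str
    sigma2_g: float
    sigma2_p: float
    sigma2_e_mean: float
    sigma2_e_plot: float
    h2: float
    cv_g: float
    cv_e: float
    vi: float
    negative_sigma2g: bool


def fit_rcbd_anova(table: PhenotypeTable, trait_id: str) -> AnovaRow:
    """Two-way (genotype + block) ANOVA for one trait.

    Requires a balanced layout: every genotype observed in every block.
    F for genotypes is MSG/MSE on (g-1, (g-1)(r-1)) degrees of freedom.
    """
    mat = table.plot_matrix(trait_id)
    missing = table.missing_cells(trait_id)
    if missing:
        raise ValueError(
            f"unbalanced layout for trait {trait_id!r}: missing cells {missing[:10]}"
            + ("..." if len(missing) > 10 else "")
        )
    y = mat.to_numpy(float)
    g, r = y.shape
    if g < 2 or r < 2:
        raise ValueError(f"need at least 2 genotypes and 2 blocks, got g={g}, r={r}")
    grand = y.mean()
    ss_total = float(((y - grand) ** 2).sum())
    ss_geno = float(r * ((y.mean(axis=1) - grand) ** 2).sum())
    ss_block = float(g * ((y.mean(axis=0) - grand) ** 2).sum())
    ss_resid = max(ss_total - ss_geno - ss_block, 0.0)
    df_g, df_b = g - 1, r - 1
    df_e = df_g * df_b
    ms_g, ms_b, ms_e = ss_geno / df_g, ss_block / df_b, ss_resid / df_e
    if ms_e > 0:
        f = ms_g / ms_e
        p = float(stats.f.sf(f, df_g, df_e))
    else:
        f, p = math.inf, 0.0
        warnings.warn(
            f"zero residual mean square for trait {trait_id!r}; F reported as inf",
            stacklevel=2,
        )
    if grand == 0:
        cv = math.nan
    else:
        cv = 100.0 * math.sqrt(ms_e) / abs(grand)
    return AnovaRow(
        trait_id=trait_id,
        g=g,
        r=r,
        df_blocks=df_b,
        df_genotypes=df_g,
        df_residual=df_e,
        df_total=g * r - 1,
        ms_blocks=ms_b,
        ms_genotypes=ms_g,
        ms_residual=ms_e,
        f_genotypes=f,
        p_genotypes=p,
        cv_pct=cv,
        grand_mean=float(grand),
    )


def estimate_genetic_parameters(
    row: AnovaRow, r: int | None = None, *, cve_level: str = "plot"
) -> GeneticParameters:
    """Genetic parameters at the genotype-mean level from one ANOVA row.

    Negative sigma2_g (MSG < MSE) is reported as computed with a flag
    set; it is clamped to zero only inside h2 and CVg, so the estimate
    itself stays transparent.
    """
    r = int(r if r is not None else row.r)
    if r < 2:
        raise ValueError(f"replicate count must be >= 2, got {r}")
    if cve_level not in ("plot", "mean"):
        raise ValueError("cve_level must be 'plot' or 'mean'")
    msg, mse = row.ms_genotypes, row.ms_residual
    sigma2_g = (msg - mse) / r
    sigma2_p = msg / r
    sigma2_e_mean = mse / r
    negative = sigma2_g < 0
    h2 = 0.0 if sigma2_p <= 0 else min(max(sigma2_g / sigma2_p, 0.0), 1.0)
    if row.grand_mean == 0:
        raise ValueError(
            f"grand mean is zero for trait {row.trait_id!r}; CV terms undefined"
        )
    mean = abs(row.grand_mean)
    cv_g = 100.0 * math.sqrt(max(sigma2_g, 0.0)) / mean
    mse_for_cve = mse if cve_level == "plot" else sigma2_e_mean
    cv_e = 100.0 * math.sqrt(mse_for_cve) / mean
    vi = cv_g / cv_e if cv_e > 0 else math.nan
    return GeneticParameters(
        trait_id=row.trait_id,
        sigma2_g=sigma2_g,
        sigma2_p=sigma2_p,
        sigma2_e_mean=sigma2_e_mean,
        sigma2_e_plot=mse,
        h2=h2,
        cv_g=cv_g,
        cv_e=cv_e,
        vi=vi,
        negative_sigma2g=negative,
    )


def anova_table(table: PhenotypeTable, traits=None) -> pd.DataFrame:
    """ANOVA rows for every (balanced) trait, as a tidy DataFrame.

    Traits with missing cells are excluded with a warning: the printed
    degrees of freedom presuppose balance and no imputation is done.
    A Bonferroni-adjusted p-value column is emitted alongside the raw
    per-trait p-values.
    """
    traits = list(traits) if traits is not None else table.traits
    rows = []
    for t in traits:
        if not table.is_balanced(t):
            warnings.warn(f"trait {t!r} is unbalanced; excluded from ANOVA", stacklevel=2)
            continue
        rows.append(fit_rcbd_anova(table, t))
    df = pd.DataFrame([vars(x) for x in rows])
    if not df.empty:
        m = len(df)
        df["p_bonferroni"] = np.minimum(df["p_genotypes"] * m, 1.0)
    return df


def genetic_parameters_table(
    anova: pd.DataFrame, r: int | None = None, *, cve_level: str = "plot"
) -> pd.DataFrame:
    rows = []
    for rec in anova.itertuples(index=False):
        row = AnovaRow(
            trait_id=rec.trait_id,
            g=rec.g,
            r=rec.r,
            df_blocks=rec.df_blocks,
            df_genotypes=rec.df_genotypes,
            df_residual=rec.df_residual,
            df_total=rec.df_total,
            ms_blocks=rec.ms_blocks,
            ms_genotypes=rec.ms_genotypes,
            ms_residual=rec.ms_residual,
            f_genotypes=rec.f_genotypes,
            p_genotypes=rec.p_genotypes,
            cv_pct=rec.cv_pct,
            grand_mean=rec.grand_mean,
        )
        rows.append(vars(estimate_genetic_parameters(row, r, cve_level=cve_level)))
    out = pd.DataFrame(rows)
    if not out.empty:
        out["h2_pct"] = 100.0 * out["h2"]
    return out
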