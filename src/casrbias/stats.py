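"""Statistical comparison of concentration-response curves.

Two procedures mirror the study design: the extra-sum-of-squares F test asks
whether a wild-type and a mutant curve can share a single EC50 (all other 4PL
parameters remain genotype-specific under the null), and fixed-effects
two-way ANOVA (genotype x concentration, with interaction) with Tukey
honestly-significant-difference comparisons across genotypes within each
concentration. ANOVA accepts balanced designs only; with plate-balanced data
the Type I/II/III sum-of-squares distinction vanishes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.optimize import least_squares
import statsmodels.api as sm
import statsmodels.formula.api as smf

from casrbias.dataset import ConcentrationResponseDataset
from casrbias.fitting import (
    LN10,
    DegenerateFitError,
    FitConvergenceError,
    HillFit,
    fit_hill,
)

ALPHA = 0.05  # study-wide significance threshold


@dataclass(frozen=True)
class FTestResult:
    """Extra-sum-of-squares F test of a shared EC50 between two genotypes."""

    genotype_a: str
    genotype_b: str
    pathway: str
    f_statistic: float
    df_numerator: int
    df_denominator: int
    p_value: float
    rss_null: float
    rss_alt: float
    logec50_a: float
    logec50_b: float
    logec50_shared: float

    @property
    def significant(self) -> bool:
        return self.p_value < ALPHA


@dataclass
class AnovaResult:
    """Two-way fixed-effects ANOVA table plus per-concentration Tukey HSD.

    ``table`` rows: genotype, concentration, interaction, residual with
    columns sum_sq, df, mean_sq, F, p. ``tukey`` has one row per
    (concentration, genotype pair) with the mean difference, studentized
    range statistic q and Tukey-adjusted p-value.
    """

    pathway: str
    table: pd.DataFrame
    tukey: pd.DataFrame
    n_per_cell: int

    @property
    def ss_total(self) -> float:
        return float(self.table["sum_sq"].sum())


# ---------------------------------------------------------------------------
# Shared-EC50 joint fit (null model of the F test)
# ---------------------------------------------------------------------------

def _null_model(params, logc_a, logc_b):
    ba, ta, sa, bb, tb, sb, le = params
    fa = ba + (ta - ba) / (1.0 + 10.0 ** ((le - logc_a) * sa))
    fb = bb + (tb - bb) / (1.0 + 10.0 ** ((le - logc_b) * sb))
    return fa, fb


def _null_residuals(params, logc_a, y_a, logc_b, y_b):
    fa, fb = _null_model(params, logc_a, logc_b)
    return np.concatenate([fa - y_a, fb - y_b])


def _null_jacobian(params, logc_a, y_a, logc_b, y_b):
    ba, ta, sa, bb, tb, sb, le = params
    n_a, n_b = logc_a.size, logc_b.size
    J = np.zeros((n_a + n_b, 7))
    for (off, logc, b, t, s, cols) in (
        (0, logc_a, ba, ta, sa, (0, 1, 2)),
        (n_a, logc_b, bb, tb, sb, (3, 4, 5)),
    ):
        u = 10.0 ** ((le - logc) * s)
        g = 1.0 / (1.0 + u)
        dg = -u * g * g * LN10
        rows = slice(off, off + logc.size)
        J[rows, cols[0]] = 1.0 - g
        J[rows, cols[1]] = g
        J[rows, cols[2]] = (t - b) * dg * (le - logc)
        J[rows, 6] += (t - b) * dg * s
    return J


def _fit_shared_ec50(sub_a: pd.DataFrame, sub_b: pd.DataFrame) -> tuple[float, float]:
    """Fit both genotypes jointly with one shared log-EC50.

    Returns (rss, shared log-EC50). Same deterministic multi-start idea as
    the single-curve fitter: shared log-EC50 starts at the pooled
    log-concentration quartiles, a common slope start of 0.5/1/3, bottoms and
    tops from each genotype's data range.
    """
    logc_a = np.log10(sub_a["conc_mM"].to_numpy(dtype=float))
    y_a = sub_a["response"].to_numpy(dtype=float)
    logc_b = np.log10(sub_b["conc_mM"].to_numpy(dtype=float))
    y_b = sub_b["response"].to_numpy(dtype=float)
    # sorted inputs keep the optimizer path independent of row order
    for arr in ("a", "b"):
        pass
    oa = np.lexsort((y_a, logc_a)); logc_a, y_a = logc_a[oa], y_a[oa]
    ob = np.lexsort((y_b, logc_b)); logc_b, y_b = logc_b[ob], y_b[ob]

    pooled = np.concatenate([logc_a, logc_b])
    lo = np.array([0.0, -np.inf, 0.1, 0.0, -np.inf, 0.1, pooled.min() - 2.0])
    hi = np.array([np.inf, np.inf, 10.0, np.inf, np.inf, 10.0, pooled.max() + 2.0])

    def span(y):
        b0 = max(float(np.min(y)), 0.0)
        t0 = float(np.max(y))
        return b0, t0 if t0 > b0 else b0 + 1.0

    ba0, ta0 = span(y_a)
    bb0, tb0 = span(y_b)
    best = None
    for q in (25.0, 50.0, 75.0):
        le0 = float(np.percentile(pooled, q))
        for s0 in (0.5, 1.0, 3.0):
            x0 = np.clip(
                np.array([ba0, ta0, s0, bb0, tb0, s0, le0]),
                lo + 1e-9,
                np.where(np.isfinite(hi), hi - 1e-9, np.array([ba0, ta0, s0, bb0, tb0, s0, le0])),
            )
            try:
                res = least_squares(
                    _null_residuals, x0, jac=_null_jacobian, bounds=(lo, hi),
                    args=(logc_a, y_a, logc_b, y_b),
                    method="trf", xtol=1e-12, ftol=1e-12, gtol=1e-12,
                )
            except Exception:
                continue
            if not np.all(np.isfinite(res.x)):
                continue
            rss = float(np.sum(res.fun ** 2))
            key = (rss, abs(res.x[2] - 1.0) + abs(res.x[5] - 1.0))
            if best is None or key < best[0]:
                best = (key, rss, float(res.x[6]))
    if best is None:
        raise FitConvergenceError("shared-EC50 joint fit did not converge from any start")
    return best[1], best[2]


def ec50_f_test(
    data_a: ConcentrationResponseDataset,
    data_b: ConcentrationResponseDataset,
    pathway: str,
) -> FTestResult:
    """Extra-sum-of-squares F test comparing EC50 between two genotypes.

    Null model: one log-EC50 shared across genotypes, all other 4PL
    parameters genotype-specific (7 parameters). Alternative: fully separate
    fits (8 parameters). ``F = ((rss0 - rss1)/(df0 - df1)) / (rss1/df1)``
    with p from the F(df0-df1, df1) distribution.

    Each input dataset must contain exactly one genotype for ``pathway``.
    """
    gen_a = data_a.select(pathway=pathway).genotypes
    gen_b = data_b.select(pathway=pathway).genotypes
    if len(gen_a) != 1 or len(gen_b) != 1:
        raise ValueError("each input must hold exactly one genotype for the pathway")
    fit_a = fit_hill(data_a, gen_a[0], pathway)
    fit_b = fit_hill(data_b, gen_b[0], pathway)
    rss_alt = fit_a.rss + fit_b.rss
    n_total = fit_a.n_points + fit_b.n_points
    df_alt = n_total - 8
    df_null = n_total - 7
    if df_alt <= 0:
        raise ValueError(f"not enough points for the F test: df_alt = {df_alt}")
    sub_a = data_a.select(gen_a[0], pathway).data
    sub_b = data_b.select(gen_b[0], pathway).data
    rss_null, le_shared = _fit_shared_ec50(sub_a, sub_b)
    # the null is nested in the alternative, so rss_null >= rss_alt up to
    # optimizer round-off; clamp tiny negative excursions to zero
    extra = max(rss_null - rss_alt, 0.0)
    f_stat = (extra / (df_null - df_alt)) / (rss_alt / df_alt)
    p = float(sps.f.sf(f_stat, df_null - df_alt, df_alt))
    return FTestResult(
        genotype_a=gen_a[0],
        genotype_b=gen_b[0],
        pathway=pathway,
        f_statistic=float(f_stat),
        df_numerator=df_null - df_alt,
        df_denominator=df_alt,
        p_value=p,
        rss_null=float(max(rss_null, rss_alt)),
        rss_alt=float(rss_alt),
        logec50_a=fit_a.logec50,
        logec50_b=fit_b.logec50,
        logec50_shared=le_shared,
    )


# ---------------------------------------------------------------------------
# Two-way ANOVA + Tukey
# ---------------------------------------------------------------------------

def two_way_anova(data: ConcentrationResponseDataset, pathway: str) -> AnovaResult:
    """Balanced two-way ANOVA (genotype x concentration) with Tukey HSD.

    Requires >= 2 levels per factor and an equal replicate count >= 2 in every
    genotype x concentration cell; unbalanced tables are rejected explicitly
    rather than silently picking a sum-of-squares type. Tukey comparisons are
    computed across genotypes within each concentration, using the pooled
    residual mean square of the full model and studentized-range p-values.
    """
    df = data.select(pathway=pathway).data.copy()
    genotypes = sorted(df["genotype"].unique())
    concs = np.sort(df["conc_mM"].unique())
    if len(genotypes) < 2 or len(concs) < 2:
        raise ValueError("need >= 2 genotypes and >= 2 concentrations")
    counts = df.groupby(["genotype", "conc_mM"]).size()
    if len(counts) != len(genotypes) * len(concs):
        raise ValueError("unbalanced design: some genotype x concentration cells are empty")
    if counts.nunique() != 1:
        raise ValueError(
            "unbalanced design: replicate counts per cell differ "
            f"(min {counts.min()}, max {counts.max()}); balanced input required"
        )
    n_cell = int(counts.iloc[0])
    if n_cell < 2:
        raise ValueError("need >= 2 replicates per cell")

    model = smf.ols("response ~ C(genotype) * C(conc_mM)", data=df).fit()
    aov = sm.stats.anova_lm(model, typ=2)
    # balanced design: type I/II/III coincide
    table = pd.DataFrame(
        {
            "factor": ["genotype", "concentration", "interaction", "residual"],
            "sum_sq": [
                aov.loc["C(genotype)", "sum_sq"],
                aov.loc["C(conc_mM)", "sum_sq"],
                aov.loc["C(genotype):C(conc_mM)", "sum_sq"],
                aov.loc["Residual", "sum_sq"],
            ],
            "df": [
                aov.loc["C(genotype)", "df"],
                aov.loc["C(conc_mM)", "df"],
                aov.loc["C(genotype):C(conc_mM)", "df"],
                aov.loc["Residual", "df"],
            ],
            "F": [
                aov.loc["C(genotype)", "F"],
                aov.loc["C(conc_mM)", "F"],
                aov.loc["C(genotype):C(conc_mM)", "F"],
                np.nan,
            ],
            "p": [
                aov.loc["C(genotype)", "PR(>F)"],
                aov.loc["C(conc_mM)", "PR(>F)"],
                aov.loc["C(genotype):C(conc_mM)", "PR(>F)"],
                np.nan,
            ],
        }
    )
    table["mean_sq"] = table["sum_sq"] / table["df"]

    ms_res = table.loc[table["factor"] == "residual", "mean_sq"].iloc[0]
    df_res = int(table.loc[table["factor"] == "residual", "df"].iloc[0])
    k = len(genotypes)
    cell_means = df.groupby(["conc_mM", "genotype"])["response"].mean()
    rows = []
    for conc in concs:
        for i in range(k):
            for j in range(i + 1, k):
                g1, g2 = genotypes[i], genotypes[j]
                diff = cell_means[(conc, g1)] - cell_means[(conc, g2)]
                se = np.sqrt(ms_res / n_cell)
                q = abs(diff) / se if se > 0 else 0.0
                p_adj = float(sps.studentized_range.sf(q, k, df_res)) if q > 0 else 1.0
                rows.append((conc, g1, g2, float(diff), float(q), min(p_adj, 1.0)))
    tukey = pd.DataFrame(
        rows, columns=["conc_mM", "group1", "group2", "mean_diff", "q", "p_adj"]
    )
    return AnovaResult(pathway=pathway, table=table, tukey=tukey, n_per_cell=n_cell)
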