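"""Normalisation conventions and four-parameter logistic curve fitting.

Two normalisations mirror the plate-assay conventions: Ca2+i peak responses
are expressed as a percentage of the wild-type maximal response, and reporter
/ pERK responses as fold changes over the response at the basal agonist
concentration (0.1 mM extracellular Ca2+).

Fits minimise unweighted least squares of all replicate points against the
4PL in log10 concentration, with a deterministic multi-start scheme (log-EC50
started at the observed log-concentration quartiles, Hill slope at 0.5/1/3,
bottom/top from the data range). Emax is the fitted top parameter.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

from casrbias.dataset import ConcentrationResponseDataset, Scale

LN10 = np.log(10.0)

#: default box constraints: bottom >= 0, Hill slope in [0.1, 10], log-EC50
#: within a generous window around the observed concentrations
DEFAULT_SLOPE_BOUNDS = (0.1, 10.0)


class DegenerateFitError(RuntimeError):
    """Raised when the data cannot identify a sigmoid (e.g. flat responses)."""


class FitConvergenceError(RuntimeError):
    """Raised when no start of the multi-start scheme converges."""


@dataclass(frozen=True)
class HillFit:
    """Fitted 4PL parameters for one genotype x pathway.

    ``top`` is the Emax; ``logec50`` is log10 EC50 (mM). ``rss`` is the
    residual sum of squares over all replicate points, ``dof`` the residual
    degrees of freedom (n_points - 4).
    """

    genotype: str
    pathway: str
    bottom: float
    top: float
    logec50: float
    hill_slope: float
    rss: float
    n_points: int
    converged: bool

    @property
    def ec50(self) -> float:
        return 10.0 ** self.logec50

    @property
    def emax(self) -> float:
        return self.top

    @property
    def dof(self) -> int:
        return self.n_points - 4

    def params(self) -> np.ndarray:
        return np.array([self.bottom, self.top, self.logec50, self.hill_slope])


# ---------------------------------------------------------------------------
# Normalisation
# ---------------------------------------------------------------------------

def normalize_to_wt_max(
    data: ConcentrationResponseDataset, wt_label: str = "WT"
) -> ConcentrationResponseDataset:
    """Express every response as a percentage of the wild-type maximum.

    The wild-type maximum statistic is, per pathway, the largest
    per-concentration mean response of the ``wt_label`` genotype; it maps to
    exactly 100. Responses are not clipped: gain-of-function constructs may
    exceed 100%.
    """
    if data.scale is not Scale.RAW:
        raise ValueError(f"expected raw-scale data, got {data.scale.value}")
    df = data.data
    if wt_label not in set(df["genotype"]):
        raise KeyError(f"wild-type label {wt_label!r} not in dataset")
    out = df.copy()
    for pathway, sub in df.groupby("pathway"):
        wt = sub[sub["genotype"] == wt_label]
        if len(wt) == 0:
            raise KeyError(f"wild-type label {wt_label!r} has no data for pathway {pathway!r}")
        wt_max = wt.groupby("conc_mM")["response"].mean().max()
        if wt_max <= 0:
            raise ValueError(
                f"wild-type maximum response is non-positive for pathway {pathway!r}; "
                "normalisation undefined"
            )
        mask = out["pathway"] == pathway
        out.loc[mask, "response"] = out.loc[mask, "response"] / wt_max * 100.0
    return ConcentrationResponseDataset(out, scale=Scale.PERCENT_OF_WT_MAX)


def fold_change_over_basal(
    data: ConcentrationResponseDataset, basal_conc: float = 0.1
) -> ConcentrationResponseDataset:
    """Express responses as fold changes over the basal-concentration mean.

    Each response is divided by the mean response of its own
    (genotype, pathway) cell at ``basal_conc``; that mean maps to 1.0.
    """
    if data.scale is not Scale.RAW:
        raise ValueError(f"expected raw-scale data, got {data.scale.value}")
    df = data.data
    out = df.copy()
    for (genotype, pathway), sub in df.groupby(["genotype", "pathway"]):
        basal = sub[np.isclose(sub["conc_mM"], basal_conc)]
        if len(basal) == 0:
            raise KeyError(
                f"basal concentration {basal_conc} mM absent for ({genotype}, {pathway})"
            )
        basal_mean = basal["response"].mean()
        if basal_mean <= 0:
            raise ValueError(
                f"basal mean response {basal_mean:.4g} <= 0 for ({genotype}, {pathway}); "
                "fold change undefined"
            )
        mask = (df["genotype"] == genotype) & (df["pathway"] == pathway)
        out.loc[mask, "response"] = out.loc[mask, "response"] / basal_mean
    return ConcentrationResponseDataset(out, scale=Scale.FOLD_CHANGE_OVER_BASAL)


# ---------------------------------------------------------------------------
# 4PL least squares
# ---------------------------------------------------------------------------

def _model(params: np.ndarray, logc: np.ndarray) -> np.ndarray:
    bottom, top, logec50, slope = params
    return bottom + (top - bottom) / (1.0 + 10.0 ** ((logec50 - logc) * slope))


def _residuals(params: np.ndarray, logc: np.ndarray, y: np.ndarray) -> np.ndarray:
    return _model(params, logc) - y


def _jacobian(params: np.ndarray, logc: np.ndarray, y: np.ndarray) -> np.ndarray:
    bottom, top, logec50, slope = params
    u = 10.0 ** ((logec50 - logc) * slope)
    g = 1.0 / (1.0 + u)
    dg = -u * g * g * LN10  # d g / d[(logec50 - logc) * slope]
    J = np.empty((logc.size, 4))
    J[:, 0] = 1.0 - g
    J[:, 1] = g
    J[:, 2] = (top - bottom) * dg * slope
    J[:, 3] = (top - bottom) * dg * (logec50 - logc)
    return J


def _start_grid(logc: np.ndarray, y: np.ndarray) -> list[np.ndarray]:
    """Deterministic multi-start grid: log-EC50 at the observed
    log-concentration quartiles, slope at 0.5/1/3, bottom/top at the data
    extremes."""
    b0, t0 = float(np.min(y)), float(np.max(y))
    b0 = max(b0, 0.0)
    if t0 <= b0:
        t0 = b0 + 1.0
    starts = []
    for q in (25.0, 50.0, 75.0):
        le = float(np.percentile(logc, q))
        for s in (0.5, 1.0, 3.0):
            starts.append(np.array([b0, t0, le, s]))
    return starts


def fit_hill(
    data: ConcentrationResponseDataset,
    genotype: str,
    pathway: str,
    bounds: tuple[Sequence[float], Sequence[float]] | None = None,
) -> HillFit:
    """Least-squares 4PL fit for one genotype x pathway.

    All replicate points enter the objective (no pre-averaging), preserving
    residual degrees of freedom for the extra-sum-of-squares F test. The fit
    is deterministic: every start of the documented multi-start grid is run
    and the lowest residual sum of squares wins; exact ties are broken toward
    the Hill slope closest to 1.

    Parameters
    ----------
    bounds:
        Optional ``(lower, upper)`` 4-vectors over (bottom, top, logec50,
        hill_slope). Defaults: bottom in [0, inf), top free, log-EC50 within
        +/- 2 decades of the observed concentration range, slope in [0.1, 10].

    Raises
    ------
    DegenerateFitError
        If the responses have zero variance (flat data cannot identify EC50).
    FitConvergenceError
        If no start converges.
    """
    sub = data.select(genotype, pathway).data
    conc = sub["conc_mM"].to_numpy(dtype=float)
    y = sub["response"].to_numpy(dtype=float)
    n_conc = np.unique(conc).size
    if len(sub) < 5 or n_conc < 4:
        raise ValueError(
            f"({genotype}, {pathway}): need >= 5 points over >= 4 concentrations, "
            f"got {len(sub)} points over {n_conc}"
        )
    if np.ptp(y) == 0 or np.var(y) == 0:
        raise DegenerateFitError(
            f"({genotype}, {pathway}): responses are constant ({y[0]:.4g}); "
            "no concentration dependence to fit"
        )
    # sort for order-independence of the optimizer trajectory
    order = np.lexsort((y, conc))
    logc = np.log10(conc[order])
    y = y[order]

    if bounds is None:
        lo = np.array([0.0, -np.inf, logc.min() - 2.0, DEFAULT_SLOPE_BOUNDS[0]])
        hi = np.array([np.inf, np.inf, logc.max() + 2.0, DEFAULT_SLOPE_BOUNDS[1]])
    else:
        lo, hi = (np.asarray(b, dtype=float) for b in bounds)

    best = None
    for x0 in _start_grid(logc, y):
        x0 = np.clip(x0, lo + 1e-9, np.where(np.isfinite(hi), hi - 1e-9, x0))
        try:
            res = least_squares(
                _residuals, x0, jac=_jacobian, bounds=(lo, hi), args=(logc, y),
                method="trf", xtol=1e-12, ftol=1e-12, gtol=1e-12,
            )
        except Exception:
            continue
        if not np.all(np.isfinite(res.x)):
            continue
        rss = float(np.sum(res.fun ** 2))
        key = (rss, abs(res.x[3] - 1.0))
        if best is None or key < best[0]:
            best = (key, res)
    if best is None:
        raise FitConvergenceError(
            f"({genotype}, {pathway}): no start of the multi-start scheme converged"
        )
    res = best[1]
    bottom, top, logec50, slope = (float(v) for v in res.x)
    return HillFit(
        genotype=genotype,
        pathway=pathway,
        bottom=bottom,
        top=top,
        logec50=logec50,
        hill_slope=slope,
        rss=float(np.sum(res.fun ** 2)),
        n_points=len(y),
        converged=bool(res.status > 0),
    )


def fit_all(data: ConcentrationResponseDataset) -> list[HillFit]:
    """Fit every genotype x pathway cell present in the dataset.

    Degenerate cells raise; callers wanting partial results should catch
    :class:`DegenerateFitError` per cell (the pipeline does).
    """
    fits = []
    for genotype in data.genotypes:
        for pathway in data.select(genotype).pathways:
            fits.append(fit_hill(data, genotype, pathway))
    return fits
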