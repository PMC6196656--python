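"""Signalling-bias quantification from paired-pathway curve fits.

For each construct the intrinsic relative activity compares the two pathways,

    RA = (Emax_Ca * EC50_pERK) / (EC50_Ca * Emax_pERK),

and the bias factor expresses it relative to wild type,

    bias factor = log10(RA_mutant / RA_WT).

A positive factor means the construct favours Ca2+i mobilisation relative to
wild type; a negative factor favours the MAPK (pERK) arm. Bias plots pair the
per-concentration mean responses of the two pathways (Ca2+i on x, pERK on y,
both as % of wild-type maximum); points above the line of identity indicate
pERK-leaning responses and points below Ca2+i-leaning ones, and a construct is
classified by the signed mean deviation from that line. Constructs with a
degenerate pathway (e.g. an absent pERK response) are reported as undefined
with a reason rather than as an infinite factor.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from casrbias.dataset import ConcentrationResponseDataset
from casrbias.fitting import HillFit

CLASSIFICATIONS = ("Ca_biased", "pERK_biased", "unbiased", "undefined")

#: default half-width of the "unbiased" band on the %-of-WT response scale
DEFAULT_TOLERANCE = 5.0


class UndefinedBiasError(ValueError):
    """Raised when RA or a bias factor is not computable; carries the reason."""


@dataclass(frozen=True)
class BiasResult:
    """Per-construct bias summary relative to wild type."""

    genotype: str
    ra: float | None
    bias_factor: float | None
    classification: str
    ra_raw: float | None = None
    undefined_reason: str | None = None

    def __post_init__(self) -> None:
        if self.classification not in CLASSIFICATIONS:
            raise ValueError(f"unknown classification {self.classification!r}")


@dataclass(frozen=True)
class BiasPlotSeries:
    """Paired mean responses of the two pathways on a shared agonist grid."""

    genotype: str
    concentrations: tuple[float, ...]
    x: tuple[float, ...]  # Ca2+i mean response, % of WT max
    y: tuple[float, ...]  # pERK mean response, % of WT max
    signed_area: float
    mean_deviation: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "genotype": self.genotype,
                "conc_mM": self.concentrations,
                "ca_response": self.x,
                "perk_response": self.y,
            }
        )


def _check_fit(fit: HillFit, role: str) -> None:
    if not fit.converged:
        raise UndefinedBiasError(f"{role} fit did not converge")
    if not np.isfinite(fit.logec50):
        raise UndefinedBiasError(f"{role} EC50 is not finite")
    if fit.top <= fit.bottom:
        raise UndefinedBiasError(f"{role} pathway has no response (top <= bottom)")
    if fit.top <= 0:
        raise UndefinedBiasError(f"{role} Emax is non-positive")
    # an absent response fitted through noise has a dynamic range comparable
    # to the residual scatter; refuse to turn that into an RA
    if fit.dof > 0:
        noise = np.sqrt(fit.rss / fit.dof)
        if fit.top - fit.bottom < 3.0 * noise:
            raise UndefinedBiasError(
                f"{role} dynamic range ({fit.top - fit.bottom:.3g}) is within 3x the "
                f"residual noise ({noise:.3g}); response indistinguishable from flat"
            )


def intrinsic_relative_activity(fit_ca: HillFit, fit_perk: HillFit) -> float:
    """RA = (Emax_Ca * EC50_pERK) / (EC50_Ca * Emax_pERK) for one construct.

    Both fits must be converged sigmoids with a positive dynamic range;
    otherwise :class:`UndefinedBiasError` carries the reason (extreme bias,
    RA not computable) instead of a fabricated number.
    """
    _check_fit(fit_ca, "Ca2+i")
    _check_fit(fit_perk, "pERK")
    return (fit_ca.emax * fit_perk.ec50) / (fit_ca.ec50 * fit_perk.emax)


def bias_factor(ra_mut: float, ra_wt: float) -> float:
    """log10(RA_mutant / RA_WT); positive favours Ca2+i relative to WT."""
    if ra_mut is None or ra_wt is None or not (ra_mut > 0 and ra_wt > 0):
        raise UndefinedBiasError(
            f"RA values must be defined and > 0 (got mutant {ra_mut!r}, WT {ra_wt!r})"
        )
    return float(np.log10(ra_mut / ra_wt))


def bias_plot_points(
    ca_data: ConcentrationResponseDataset,
    perk_data: ConcentrationResponseDataset,
    genotype: str,
) -> BiasPlotSeries:
    """Pair the per-concentration mean responses of the two pathways.

    Both inputs must be on the same (WT-normalised) scale and share an
    identical concentration grid; a mismatch is reported listing the
    offending concentrations. The series carries the signed trapezoidal area
    between the (x, y) curve and the identity line over log10 concentration,
    and the signed mean deviation (x - y) used for classification.
    """
    ca = ca_data.select(genotype, "Ca").cell_means()
    perk = perk_data.select(genotype, "pERK").cell_means()
    conc_ca = ca["conc_mM"].to_numpy()
    conc_perk = perk["conc_mM"].to_numpy()
    if len(conc_ca) != len(conc_perk) or not np.allclose(conc_ca, conc_perk):
        only_ca = sorted(set(np.round(conc_ca, 9)) - set(np.round(conc_perk, 9)))
        only_perk = sorted(set(np.round(conc_perk, 9)) - set(np.round(conc_ca, 9)))
        raise ValueError(
            f"concentration grids differ for {genotype!r}: "
            f"Ca-only {only_ca} vs pERK-only {only_perk}"
        )
    x = ca["response"].to_numpy()
    y = perk["response"].to_numpy()
    dev = x - y
    logc = np.log10(conc_ca)
    area = float(np.trapezoid(dev, logc)) if len(dev) > 1 else float(dev[0])
    return BiasPlotSeries(
        genotype=genotype,
        concentrations=tuple(float(c) for c in conc_ca),
        x=tuple(float(v) for v in x),
        y=tuple(float(v) for v in y),
        signed_area=area,
        mean_deviation=float(np.mean(dev)),
    )


def classify_bias(series: BiasPlotSeries, tolerance: float = DEFAULT_TOLERANCE) -> str:
    """Classify a bias-plot series by its signed mean deviation from identity.

    ``Ca_biased`` if mean(x - y) > tolerance, ``pERK_biased`` if
    < -tolerance, else ``unbiased``. Tolerance is in response units
    (% of WT maximum by convention).
    """
    if len(series.concentrations) == 0:
        raise ValueError("empty bias-plot series")
    if series.mean_deviation > tolerance:
        return "Ca_biased"
    if series.mean_deviation < -tolerance:
        return "pERK_biased"
    return "unbiased"


def compute_bias_table(
    fits: Sequence[HillFit],
    wt_label: str = "WT",
    fits_raw: Sequence[HillFit] | None = None,
    classifications: Mapping[str, str] | None = None,
) -> list[BiasResult]:
    """Build the per-genotype bias table from paired-pathway fits.

    ``fits`` are the fits on the WT-normalised percent scale (the scale RA is
    reported on); ``fits_raw`` optionally supplies raw-scale fits whose RA is
    emitted alongside for transparency. ``classifications`` may carry
    bias-plot classifications per genotype (the pipeline passes these);
    genotypes without one are classified by the sign of their bias factor.
    The wild type's factor is exactly 0 by construction.
    """
    by_cell = {(f.genotype, f.pathway): f for f in fits}
    raw_by_cell = {(f.genotype, f.pathway): f for f in (fits_raw or [])}
    genotypes = sorted({f.genotype for f in fits})
    if wt_label not in genotypes:
        raise KeyError(f"wild-type label {wt_label!r} absent from fits")

    def ra_for(genotype: str, table: dict) -> float:
        fit_ca = table.get((genotype, "Ca"))
        fit_perk = table.get((genotype, "pERK"))
        if fit_ca is None or fit_perk is None:
            missing = "Ca2+i" if fit_ca is None else "pERK"
            raise UndefinedBiasError(f"{missing} fit missing for {genotype!r}")
        return intrinsic_relative_activity(fit_ca, fit_perk)

    ra_wt = ra_for(wt_label, by_cell)  # WT must be well-defined
    results = []
    for genotype in genotypes:
        try:
            ra = ra_for(genotype, by_cell)
            bf = 0.0 if genotype == wt_label else bias_factor(ra, ra_wt)
        except UndefinedBiasError as exc:
            results.append(
                BiasResult(
                    genotype=genotype,
                    ra=None,
                    bias_factor=None,
                    classification="undefined",
                    undefined_reason=f"extreme bias, RA not computable: {exc}",
                )
            )
            continue
        ra_raw = None
        if raw_by_cell:
            try:
                ra_raw = ra_for(genotype, raw_by_cell)
            except UndefinedBiasError:
                ra_raw = None
        if classifications and genotype in classifications:
            label = classifications[genotype]
        else:
            label = "Ca_biased" if bf > 0 else ("pERK_biased" if bf < 0 else "unbiased")
        results.append(
            BiasResult(
                genotype=genotype,
                ra=float(ra),
                bias_factor=float(bf),
                classification=label,
                ra_raw=None if ra_raw is None else float(ra_raw),
            )
        )
    return results


def bias_table_frame(results: Sequence[BiasResult]) -> pd.DataFrame:
    """Flatten bias results into the exported CSV layout."""
    return pd.DataFrame(
        {
            "genotype": [r.genotype for r in results],
            "RA_raw": [r.ra_raw for r in results],
            "RA_percent_scale": [r.ra for r in results],
            "bias_factor": [r.bias_factor for r in results],
            "classification": [r.classification for r in results],
            "undefined_reason": [r.undefined_reason for r in results],
        }
    )
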