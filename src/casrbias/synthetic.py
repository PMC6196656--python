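"""Synthetic two-pathway concentration-response assay generator.

Emulates per-stimulus peak Ca2+i responses and fold-change pERK responses of
HEK293 cells expressing wild-type or mutant CaSR, stimulated with 0.1-10 mM
extracellular Ca2+. Responses follow a four-parameter logistic (4PL) curve in
log10 concentration with additive, homoscedastic Gaussian replicate noise.
Presets encode the mutant phenotype classes observed for disease-switch
residues: concerted loss/gain in both pathways, Ca2+i-selective loss, a
potency gain confined to pERK, and an "uncoupled" phenotype with increased
Ca2+i but reduced pERK signalling.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from casrbias.dataset import ConcentrationResponseDataset, Scale

#: default agonist grid (mM extracellular Ca2+); covers every concentration
#: used in the assays. 0 mM is never generated: fitting is on a log scale and
#: basal is defined as 0.1 mM.
DEFAULT_CONCENTRATIONS: tuple[float, ...] = (0.1, 0.5, 1.0, 2.0, 2.5, 3.0, 5.0, 7.5, 10.0)

PATHWAYS = ("Ca", "pERK")


@dataclass(frozen=True)
class PathwayParams:
    """4PL generative parameters for one signalling pathway.

    bottom/top are in response units (the top is the generative Emax),
    ``logec50`` is log10 of the EC50 in mM, and ``hill_slope`` is the
    dimensionless steepness (must be > 0 for an agonist curve).
    """

    bottom: float
    top: float
    logec50: float
    hill_slope: float

    def __post_init__(self) -> None:
        if self.hill_slope <= 0:
            raise ValueError(f"hill_slope must be > 0, got {self.hill_slope}")
        if self.top < self.bottom:
            raise ValueError(f"top ({self.top}) must be >= bottom ({self.bottom})")

    @property
    def ec50(self) -> float:
        return 10.0 ** self.logec50

    def as_array(self) -> np.ndarray:
        return np.array([self.bottom, self.top, self.logec50, self.hill_slope])


@dataclass(frozen=True)
class PhenotypeSpec:
    """Generative description of one synthetic construct (WT or mutant)."""

    name: str
    pathways: Mapping[str, PathwayParams]
    noise_sd: float = 4.0
    n_replicates: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")

    def with_overrides(self, **kwargs) -> "PhenotypeSpec":
        return replace(self, **kwargs)


def hill_response(
    concentration: float | np.ndarray,
    bottom: float,
    top: float,
    logec50: float,
    hill_slope: float,
) -> float | np.ndarray:
    """Four-parameter logistic response at an agonist concentration (mM).

    ``bottom + (top - bottom) / (1 + 10**((logec50 - log10(c)) * hill_slope))``
    — the standard sigmoid in log10 concentration with midpoint EC50 and
    steepness ``hill_slope``. Strictly increasing in concentration when
    ``top > bottom`` and ``hill_slope > 0``.

    Raises
    ------
    ValueError
        For non-positive concentration (the curve lives on a log axis) or a
        non-positive Hill slope.
    """
    conc = np.asarray(concentration, dtype=float)
    if np.any(conc <= 0):
        raise ValueError("concentration must be > 0 mM")
    if hill_slope <= 0:
        raise ValueError("hill_slope must be > 0")
    out = bottom + (top - bottom) / (1.0 + 10.0 ** ((logec50 - np.log10(conc)) * hill_slope))
    return float(out) if np.isscalar(concentration) else out


def generate_dataset(
    spec: PhenotypeSpec,
    concentrations: Sequence[float] = DEFAULT_CONCENTRATIONS,
) -> ConcentrationResponseDataset:
    """Simulate replicate-level responses for one construct over both pathways.

    For every pathway x concentration x replicate the response is the 4PL mean
    plus one Gaussian(0, noise_sd) draw. All randomness flows from a generator
    seeded with ``spec.seed``, so identical inputs reproduce the dataset
    bit for bit.
    """
    conc = np.asarray(list(concentrations), dtype=float)
    if conc.size == 0:
        raise ValueError("concentration list is empty")
    if np.any(conc <= 0):
        raise ValueError("concentrations must be > 0 mM")
    if np.any(np.diff(conc) <= 0):
        raise ValueError("concentrations must be sorted strictly increasing")

    rng = np.random.default_rng(spec.seed)
    rows = []
    for pathway in sorted(spec.pathways):
        p = spec.pathways[pathway]
        mean = hill_response(conc, p.bottom, p.top, p.logec50, p.hill_slope)
        noise = rng.normal(0.0, spec.noise_sd, size=(spec.n_replicates, conc.size))
        for rep in range(spec.n_replicates):
            for j, c in enumerate(conc):
                rows.append((spec.name, pathway, c, rep + 1, mean[j] + noise[rep, j]))
    df = pd.DataFrame(rows, columns=["genotype", "pathway", "conc_mM", "replicate", "response"])
    return ConcentrationResponseDataset(df, scale=Scale.RAW)


def generate_cohort(
    specs: Sequence[PhenotypeSpec],
    concentrations: Sequence[float] = DEFAULT_CONCENTRATIONS,
) -> ConcentrationResponseDataset:
    """Concatenate independently generated constructs into one raw dataset."""
    parts = [generate_dataset(s, concentrations).data for s in specs]
    return ConcentrationResponseDataset(pd.concat(parts, ignore_index=True), scale=Scale.RAW)


# ---------------------------------------------------------------------------
# Phenotype presets
# ---------------------------------------------------------------------------

# Wild-type reference. The Ca2+i pathway is generated on a scale where the
# fitted top is ~100 (percent-of-WT-maximum convention); pERK on an arbitrary
# assay scale. Both pathways share EC50 3.0 mM, Hill slope 2 (a realistic
# midpoint/steepness for extracellular-Ca2+ activation of the receptor) and
# the same basal fraction (bottom/top = 5%), so the WT bias plot overlays the
# identity line by construction, as it must for the reference construct.
_WT_CA = PathwayParams(bottom=5.0, top=100.0, logec50=np.log10(3.0), hill_slope=2.0)
_WT_PERK = PathwayParams(bottom=4.0, top=80.0, logec50=np.log10(3.0), hill_slope=2.0)

_SHIFT = np.log10(2.0)  # one 2-fold potency step

def _presets() -> dict[str, PhenotypeSpec]:
    wt = PhenotypeSpec("WT", {"Ca": _WT_CA, "pERK": _WT_PERK})
    ca, perk = _WT_CA, _WT_PERK
    return {
        # identity reference
        "WT": wt,
        # concerted loss of function: right-shifted, blunted in both pathways
        "loss_both": wt.with_overrides(
            name="loss_both",
            pathways={
                "Ca": replace(ca, logec50=ca.logec50 + _SHIFT, top=0.7 * ca.top),
                "pERK": replace(perk, logec50=perk.logec50 + _SHIFT, top=0.7 * perk.top),
            },
        ),
        # concerted gain of function: left-shifted, elevated maxima
        "gain_both": wt.with_overrides(
            name="gain_both",
            pathways={
                "Ca": replace(ca, logec50=ca.logec50 - _SHIFT, top=1.3 * ca.top),
                "pERK": replace(perk, logec50=perk.logec50 - _SHIFT, top=1.3 * perk.top),
            },
        ),
        # impaired Ca2+i signalling with untouched pERK (Asn178Asp/Ser820Ala-like)
        "loss_Ca_only": wt.with_overrides(
            name="loss_Ca_only",
            pathways={
                "Ca": replace(ca, logec50=ca.logec50 + _SHIFT, top=0.7 * ca.top),
                "pERK": perk,
            },
        ),
        # potency gain confined to the MAPK arm (Gln27Glu-like)
        "gain_pERK_shift": wt.with_overrides(
            name="gain_pERK_shift",
            pathways={
                "Ca": ca,
                "pERK": replace(perk, logec50=perk.logec50 - _SHIFT),
            },
        ),
        # uncoupled phenotype: raised Ca2+i maximum, reduced pERK maximum
        # (Ser657Cys-like)
        "uncoupled_gainCa_losspERK": wt.with_overrides(
            name="uncoupled_gainCa_losspERK",
            pathways={
                "Ca": replace(ca, top=1.3 * ca.top),
                "pERK": replace(perk, top=0.6 * perk.top),
            },
        ),
    }


PRESET_NAMES: tuple[str, ...] = tuple(_presets())


def preset_phenotype(name: str, seed: int = 0, n_replicates: int | None = None,
                     noise_sd: float | None = None) -> PhenotypeSpec:
    """Return the generative spec for a named phenotype class.

    Valid names: WT, loss_both, gain_both, loss_Ca_only, gain_pERK_shift,
    uncoupled_gainCa_losspERK. Seed/replicates/noise may be overridden
    without touching the curve parameters.
    """
    table = _presets()
    if name not in table:
        raise KeyError(
            f"unknown phenotype preset {name!r}; valid presets: {', '.join(table)}"
        )
    spec = table[name].with_overrides(seed=seed)
    if n_replicates is not None:
        spec = spec.with_overrides(n_replicates=n_replicates)
    if noise_sd is not None:
        spec = spec.with_overrides(noise_sd=noise_sd)
    return spec
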