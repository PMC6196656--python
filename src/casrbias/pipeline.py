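"""End-to-end orchestration: ingest/generate -> normalise -> fit -> compare ->
bias -> report.

A declarative :class:`PipelineConfig` (YAML on disk) drives the run; all
randomness flows from its seed, so re-running an identical config reproduces
every output table bit for bit. Partial failures (a degenerate pathway, an
unbalanced ANOVA table) are recorded per genotype in the report instead of
aborting the run. Outputs are flat CSV tables plus a plain-text log.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from casrbias._version import __version__ as _version
from casrbias.bias import (
    BiasResult,
    bias_plot_points,
    bias_table_frame,
    classify_bias,
    compute_bias_table,
    DEFAULT_TOLERANCE,
)
from casrbias.dataset import ConcentrationResponseDataset, Scale, read_crc_csv
from casrbias.fitting import (
    DegenerateFitError,
    FitConvergenceError,
    HillFit,
    fit_hill,
    normalize_to_wt_max,
)
from casrbias.stats import ALPHA, AnovaResult, FTestResult, ec50_f_test, two_way_anova
from casrbias.synthetic import (
    DEFAULT_CONCENTRATIONS,
    generate_cohort,
    preset_phenotype,
)

logger = logging.getLogger("casrbias.pipeline")


class ConfigError(ValueError):
    """Raised for an invalid pipeline configuration before any computation."""


@dataclass
class PipelineConfig:
    """Declarative description of one pipeline run."""

    presets: Sequence[str] | None = None  # synthetic input: phenotype presets
    seed: int = 0
    input_csv: str | None = None  # or a plate CSV (raw scale)
    wt_label: str = "WT"
    pathway_pair: tuple[str, str] = ("Ca", "pERK")
    basal_conc: float = 0.1
    alpha: float = ALPHA
    bias_tolerance: float = DEFAULT_TOLERANCE
    n_replicates: int | None = None
    noise_sd: float | None = None
    concentrations: Sequence[float] = DEFAULT_CONCENTRATIONS
    output_dir: str = "results/run"

    def __post_init__(self) -> None:
        self.pathway_pair = tuple(self.pathway_pair)  # type: ignore[assignment]
        if len(self.pathway_pair) != 2 or self.pathway_pair[0] == self.pathway_pair[1]:
            raise ConfigError(f"pathway pair must be two distinct labels, got {self.pathway_pair}")
        if self.presets is None and self.input_csv is None:
            raise ConfigError("config needs either presets or input_csv")

    # -- round-trip --------------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["pathway_pair"] = list(self.pathway_pair)
        d["concentrations"] = [float(c) for c in self.concentrations]
        d["presets"] = list(self.presets) if self.presets is not None else None
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {', '.join(sorted(unknown))}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
        return path


@dataclass
class RunReport:
    """All tables of one pipeline run plus provenance."""

    fits: pd.DataFrame
    f_tests: pd.DataFrame
    anova: dict[str, AnovaResult]
    bias: pd.DataFrame
    series: pd.DataFrame
    failures: pd.DataFrame
    provenance: dict

    def write(self, outdir: str | Path) -> Path:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.fits.to_csv(outdir / "hill_fits.csv", index=False)
        self.f_tests.to_csv(outdir / "ec50_f_tests.csv", index=False)
        for pathway, res in self.anova.items():
            res.table.to_csv(outdir / f"anova_{pathway}.csv", index=False)
            res.tukey.to_csv(outdir / f"tukey_{pathway}.csv", index=False)
        self.bias.to_csv(outdir / "bias_table.csv", index=False)
        self.series.to_csv(outdir / "bias_plot_series.csv", index=False)
        self.failures.to_csv(outdir / "failures.csv", index=False)
        (outdir / "provenance.json").write_text(json.dumps(self.provenance, indent=2))
        lines = [
            f"casrbias {self.provenance['version']} run",
            f"genotypes: {', '.join(self.provenance['genotypes'])}",
            f"fits: {len(self.fits)} | F tests: {len(self.f_tests)} | "
            f"bias rows: {len(self.bias)} | failures: {len(self.failures)}",
        ]
        (outdir / "run.log").write_text("\n".join(lines) + "\n")
        return outdir


def _fits_frame(fits: Sequence[HillFit]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "genotype": [f.genotype for f in fits],
            "pathway": [f.pathway for f in fits],
            "bottom": [f.bottom for f in fits],
            "top": [f.top for f in fits],
            "logEC50": [f.logec50 for f in fits],
            "EC50_mM": [f.ec50 for f in fits],
            "hill_slope": [f.hill_slope for f in fits],
            "rss": [f.rss for f in fits],
            "n_points": [f.n_points for f in fits],
            "dof": [f.dof for f in fits],
            "converged": [f.converged for f in fits],
        }
    )


def _load_input(config: PipelineConfig) -> ConcentrationResponseDataset:
    if config.input_csv is not None:
        data = read_crc_csv(config.input_csv)
        if data.scale is not Scale.RAW:
            raise ConfigError(f"input CSV must be raw-scale, got {data.scale.value}")
        return data
    specs = []
    for i, name in enumerate(config.presets or []):
        spec = preset_phenotype(
            name,
            seed=config.seed + i,
            n_replicates=config.n_replicates,
            noise_sd=config.noise_sd,
        )
        specs.append(spec)
    return generate_cohort(specs, config.concentrations)


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute the full analysis described by ``config``.

    Stages: load or generate raw data; normalise every pathway to the
    wild-type maximum (percent scale); fit the 4PL per genotype x pathway on
    both the percent and raw scales; extra-sum-of-squares F test on EC50 for
    each mutant against wild type per pathway; balanced two-way ANOVA with
    Tukey per pathway; bias plots, classification, RA and WT-relative bias
    factors. Every genotype appears in the bias table exactly once, as a
    number or as an explicit undefined record.
    """
    data = _load_input(config)
    wt = config.wt_label
    if wt not in data.genotypes:
        raise ConfigError(
            f"wild-type label {wt!r} absent from input genotypes {data.genotypes}"
        )
    p_ca, p_perk = config.pathway_pair
    normalized = normalize_to_wt_max(data, wt)

    failures: list[tuple[str, str, str, str]] = []  # genotype, pathway, stage, message
    fits_pct: list[HillFit] = []
    fits_raw: list[HillFit] = []
    for genotype in data.genotypes:
        for pathway in data.select(genotype).pathways:
            for scale_name, dset, store in (
                ("percent_of_WT_max", normalized, fits_pct),
                ("raw", data, fits_raw),
            ):
                try:
                    store.append(fit_hill(dset, genotype, pathway))
                except (DegenerateFitError, FitConvergenceError, ValueError) as exc:
                    failures.append((genotype, pathway, f"fit[{scale_name}]", str(exc)))
                    logger.warning("fit failed for %s/%s (%s): %s", genotype, pathway, scale_name, exc)

    # F tests: each mutant vs WT, per pathway, on the normalised scale
    f_rows = []
    for pathway in (p_ca, p_perk):
        try:
            wt_cell = normalized.select(wt, pathway)
        except KeyError:
            continue
        for genotype in data.genotypes:
            if genotype == wt:
                continue
            try:
                mut_cell = normalized.select(genotype, pathway)
                res = ec50_f_test(wt_cell, mut_cell, pathway)
            except (KeyError, DegenerateFitError, FitConvergenceError, ValueError) as exc:
                failures.append((genotype, pathway, "f_test", str(exc)))
                continue
            f_rows.append(
                {
                    "genotype": genotype,
                    "pathway": pathway,
                    "F": res.f_statistic,
                    "df_num": res.df_numerator,
                    "df_den": res.df_denominator,
                    "p_value": res.p_value,
                    "rss_null": res.rss_null,
                    "rss_alt": res.rss_alt,
                    "logEC50_WT": res.logec50_a,
                    "logEC50_mut": res.logec50_b,
                    "logEC50_shared": res.logec50_shared,
                    "significant": res.p_value < config.alpha,
                }
            )
    f_tests = pd.DataFrame(
        f_rows,
        columns=[
            "genotype", "pathway", "F", "df_num", "df_den", "p_value",
            "rss_null", "rss_alt", "logEC50_WT", "logEC50_mut",
            "logEC50_shared", "significant",
        ],
    )

    anova: dict[str, AnovaResult] = {}
    for pathway in (p_ca, p_perk):
        try:
            anova[pathway] = two_way_anova(normalized, pathway)
        except (KeyError, ValueError) as exc:
            failures.append(("*", pathway, "anova", str(exc)))

    # bias plots + classification on the normalised percent scale
    series_frames = []
    classifications: dict[str, str] = {}
    for genotype in data.genotypes:
        try:
            series = bias_plot_points(normalized, normalized, genotype)
        except (KeyError, ValueError) as exc:
            failures.append((genotype, "*", "bias_plot", str(exc)))
            continue
        classifications[genotype] = classify_bias(series, config.bias_tolerance)
        frame = series.to_frame()
        frame["classification"] = classifications[genotype]
        series_frames.append(frame)
    series_table = (
        pd.concat(series_frames, ignore_index=True)
        if series_frames
        else pd.DataFrame(columns=["genotype", "conc_mM", "ca_response", "perk_response", "classification"])
    )

    bias_results = compute_bias_table(
        fits_pct, wt_label=wt, fits_raw=fits_raw, classifications=classifications
    )
    covered = {r.genotype for r in bias_results}
    for genotype in data.genotypes:
        if genotype not in covered:
            reasons = [m for (g, _, stage, m) in failures if g == genotype and stage.startswith("fit")]
            bias_results.append(
                BiasResult(
                    genotype=genotype,
                    ra=None,
                    bias_factor=None,
                    classification="undefined",
                    undefined_reason="extreme bias, RA not computable: "
                    + (reasons[0] if reasons else "no converged fits"),
                )
            )
    bias_results.sort(key=lambda r: r.genotype)
    bias_table = bias_table_frame(bias_results)

    provenance = {
        "version": _version,
        "config": config.to_dict(),
        "genotypes": data.genotypes,
        "seed": config.seed,
        "n_records": len(data),
    }
    failures_df = pd.DataFrame(failures, columns=["genotype", "pathway", "stage", "message"])
    return RunReport(
        fits=_fits_frame(fits_pct),
        f_tests=f_tests,
        anova=anova,
        bias=bias_table,
        series=series_table,
        failures=failures_df,
        provenance=provenance,
    )
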