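"""Normalisation conventions and 4PL least-squares fitting."""

import numpy as np
import pandas as pd
import pytest

from casrbias.dataset import Scale
from casrbias.fitting import (
    DegenerateFitError,
    fit_hill,
    fold_change_over_basal,
    normalize_to_wt_max,
)
from casrbias.synthetic import (
    DEFAULT_CONCENTRATIONS,
    PathwayParams,
    PhenotypeSpec,
    generate_dataset,
    hill_response,
)
from conftest import make_dataset


def _zero_noise(params: PathwayParams, name="G", pathway="Ca", n_rep=2):
    spec = PhenotypeSpec(name, {pathway: params}, noise_sd=0.0, n_replicates=n_rep, seed=0)
    return generate_dataset(spec)


class TestNormalizeToWtMax:
    def test_wt_maximum_maps_to_100(self, wt_spec):
        data = generate_dataset(wt_spec)
        norm = normalize_to_wt_max(data, "WT")
        assert norm.scale is Scale.PERCENT_OF_WT_MAX
        for _, sub in norm.cell_means().groupby("pathway"):
            assert sub["response"].max() == pytest.approx(100.0)

    def test_linearity_for_half_scale_mutant(self):
        rows = []
        for conc in (1.0, 2.0, 4.0, 8.0):
            for rep in (1, 2):
                rows.append(("WT", "Ca", conc, rep, 10.0 * conc))
                rows.append(("mut", "Ca", conc, rep, 5.0 * conc))
        norm = normalize_to_wt_max(make_dataset(rows), "WT")
        mut = norm.select("mut").cell_means()["response"]
        assert mut.max() == pytest.approx(50.0)

    def test_zero_mutant_stays_zero(self):
        rows = [("WT", "Ca", c, 1, 10 * c) for c in (1, 2, 4, 8)]
        rows += [("mut", "Ca", c, 1, 0.0) for c in (1, 2, 4, 8)]
        norm = normalize_to_wt_max(make_dataset(rows), "WT")
        assert (norm.select("mut").data["response"] == 0).all()

    def test_nonpositive_wt_maximum_rejected(self):
        rows = [("WT", "Ca", c, 1, -1.0) for c in (1, 2, 4, 8)]
        with pytest.raises(ValueError, match="non-positive"):
            normalize_to_wt_max(make_dataset(rows), "WT")

    def test_missing_wt_label(self, wt_spec):
        data = generate_dataset(wt_spec)
        with pytest.raises(KeyError, match="Gln27"):
            normalize_to_wt_max(data, "Gln27")


class TestFoldChangeOverBasal:
    def test_flat_responses_give_unit_fold_change(self):
        rows = [("WT", "NFAT", c, r, 7.5) for c in (0.1, 1, 3, 10) for r in (1, 2)]
        out = fold_change_over_basal(make_dataset(rows), 0.1)
        assert out.scale is Scale.FOLD_CHANGE_OVER_BASAL
        assert np.allclose(out.data["response"], 1.0)

    def test_direct_ratio(self):
        rows = [("WT", "SRE", 0.1, 1, 2.0), ("WT", "SRE", 1, 1, 6.0),
                ("WT", "SRE", 3, 1, 4.0), ("WT", "SRE", 10, 1, 8.0)]
        out = fold_change_over_basal(make_dataset(rows), 0.1)
        by_conc = out.data.set_index("conc_mM")["response"]
        assert by_conc[1.0] == pytest.approx(3.0)
        assert by_conc[10.0] == pytest.approx(4.0)

    def test_saturating_fold_change_of_4pl(self):
        # bottom=25, top=100, basal 0.1 mM deep in the lower asymptote:
        # the saturating fold change approaches the 4PL ratio at 10 mM
        params = PathwayParams(25.0, 100.0, 0.0, 2.0)
        data = _zero_noise(params, pathway="NFAT")
        out = fold_change_over_basal(data, 0.1)
        top_fc = out.cell_means()["response"].max()
        expect = hill_response(10.0, 25, 100, 0.0, 2.0) / hill_response(0.1, 25, 100, 0.0, 2.0)
        assert top_fc == pytest.approx(expect, rel=1e-9)
        # asymptotic ratio is top/bottom = 4; at 10 mM the curve is ~96% there
        assert expect == pytest.approx(4.0, rel=0.05)

    def test_missing_basal_concentration_named(self):
        rows = [("WT", "SRE", c, 1, 2.0) for c in (1, 3, 5, 10)]
        with pytest.raises(KeyError, match=r"0.1 mM absent for \(WT, SRE\)"):
            fold_change_over_basal(make_dataset(rows), 0.1)

    def test_nonpositive_basal_mean_rejected(self):
        rows = [("WT", "SRE", 0.1, 1, 0.0)] + [("WT", "SRE", c, 1, 2.0) for c in (1, 3, 10)]
        with pytest.raises(ValueError, match="fold change undefined"):
            fold_change_over_basal(make_dataset(rows), 0.1)


def grid_oracle_rss(logc: np.ndarray, y: np.ndarray) -> float:
    """Independent brute-force 4PL oracle: grid logEC50 in [-2, 2] step 0.01
    and slope in [0.25, 5] step 0.05; at each node solve (bottom, top) by
    linear least squares in closed form and keep the best RSS."""
    le = np.arange(-2, 2.0001, 0.01)[:, None, None]
    s = np.arange(0.25, 5.0001, 0.05)[None, :, None]
    g = 1.0 / (1.0 + 10.0 ** ((le - logc[None, None, :]) * s))
    h = 1.0 - g
    # normal equations of y ~ b*h + t*g
    A = (h * h).sum(-1)
    B = (h * g).sum(-1)
    C = (g * g).sum(-1)
    b1 = (h * y).sum(-1)
    b2 = (g * y).sum(-1)
    det = A * C - B * B
    det = np.where(np.abs(det) < 1e-300, np.nan, det)
    bottom = (b1 * C - b2 * B) / det
    top = (A * b2 - B * b1) / det
    rss = (y * y).sum() - (bottom * b1 + top * b2)
    return float(np.nanmin(rss))


# 20 generating parameter sets spanning the plausible assay space
RECOVERY_GRID = [
    PathwayParams(b, t, le, s)
    for b, t in [(0.0, 100.0), (5.0, 80.0), (10.0, 120.0), (2.0, 60.0)]
    for le, s in [(np.log10(0.5), 1.0), (0.0, 2.0), (np.log10(3.0), 0.8),
                  (np.log10(5.0), 3.0), (np.log10(2.0), 1.5)]
]


class TestFitHill:
    @pytest.mark.parametrize("params", RECOVERY_GRID)
    def test_zero_noise_recovery(self, params):
        """Noise-free data on the default grid returns the generating
        parameters to <= 1e-4 relative error."""
        fit = fit_hill(_zero_noise(params), "G", "Ca")
        truth = params.as_array()
        est = fit.params()
        scale = np.where(np.abs(truth) > 1e-12, np.abs(truth), params.top - params.bottom)
        assert np.all(np.abs(est - truth) / scale <= 1e-4)
        assert fit.converged and fit.rss < 1e-6

    def test_permutation_invariance(self, wt_spec):
        data = generate_dataset(wt_spec)
        shuffled = data.data.sample(frac=1.0, random_state=3).reset_index(drop=True)
        fit_a = fit_hill(data, "WT", "Ca")
        fit_b = fit_hill(make_dataset(shuffled.itertuples(index=False)), "WT", "Ca")
        assert fit_a.params() == pytest.approx(fit_b.params(), rel=0, abs=0)

    def test_scale_equivariance(self, wt_spec):
        data = generate_dataset(wt_spec)
        c = 3.7
        scaled = data.with_responses(data.data["response"] * c, Scale.RAW)
        f1 = fit_hill(data, "WT", "Ca")
        f2 = fit_hill(scaled, "WT", "Ca")
        assert f2.bottom == pytest.approx(c * f1.bottom, rel=1e-6, abs=1e-6)
        assert f2.top == pytest.approx(c * f1.top, rel=1e-6)
        assert f2.logec50 == pytest.approx(f1.logec50, abs=1e-6)
        assert f2.hill_slope == pytest.approx(f1.hill_slope, rel=1e-5)
        assert f2.rss == pytest.approx(c * c * f1.rss, rel=1e-5)

    def test_flat_data_is_degenerate(self):
        rows = [("G", "Ca", c, r, 50.0) for c in (0.5, 1, 3, 10) for r in (1, 2)]
        with pytest.raises(DegenerateFitError, match="constant"):
            fit_hill(make_dataset(rows), "G", "Ca")

    def test_too_few_concentrations_rejected(self):
        rows = [("G", "Ca", c, r, v) for (c, v) in ((1, 10.0), (3, 50.0), (10, 90.0))
                for r in (1, 2)]
        with pytest.raises(ValueError, match=">= 4 concentrations"):
            fit_hill(make_dataset(rows), "G", "Ca")

    def test_optimizer_dominates_grid_oracle(self):
        """The continuous optimizer must reach an RSS no worse than a dense
        grid search over (logEC50, slope) with (bottom, top) solved by linear
        least squares at each node."""
        params = PathwayParams(5.0, 100.0, np.log10(3.0), 2.0)
        for seed in range(6):
            spec = PhenotypeSpec("G", {"Ca": params}, noise_sd=5.0, n_replicates=6, seed=seed)
            data = generate_dataset(spec)
            fit = fit_hill(data, "G", "Ca")
            sub = data.select("G", "Ca").data
            logc = np.log10(sub["conc_mM"].to_numpy())
            y = sub["response"].to_numpy()
            best = grid_oracle_rss(logc, y)
            assert fit.rss <= best + 1e-9, f"seed {seed}: {fit.rss} > {best}"
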