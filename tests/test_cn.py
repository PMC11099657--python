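import numpy as np
import pytest

from meioseq.cn import (
    BinnedCounts,
    NormalizationError,
    build_panel,
    call_profile,
    filter_bins,
    fold_change,
    normalize,
    observed_cn,
    qc_sample,
    read_counts_tsv,
    write_counts_tsv,
)
from meioseq.genome import make_binning
from meioseq.simulate import (
    ChromatidConfiguration,
    SimulationConfig,
    simulate_normal_panel,
    simulate_read_counts,
)
from conftest import observed_pair


# --- sample QC ------------------------------------------------------------


def _sample(binning, fill=100.0, mapped=0.95, **kw):
    return BinnedCounts(
        "s", np.full(binning.n_bins, fill), mapped_fraction=mapped, **kw
    )


def test_qc_threshold(small_binning):
    assert qc_sample(_sample(small_binning, mapped=0.95)).passed
    res = qc_sample(_sample(small_binning, mapped=0.89))
    assert res.status == "fail" and "0.890" in res.reason
    # exactly at threshold passes (rule is strictly-below)
    assert qc_sample(_sample(small_binning, mapped=0.90)).passed


def test_qc_missing_mapped_fraction_is_indeterminate(small_binning):
    res = qc_sample(_sample(small_binning, mapped=None))
    assert res.status == "indeterminate"
    assert not res.passed


# --- bin filtering --------------------------------------------------------


def test_filter_bins_boundary(small_binning):
    sample = _sample(small_binning, fill=1000.0)
    assert filter_bins(sample) == {}
    sample.counts[4] = 1001
    assert filter_bins(sample) == {4: "overrepresented"}


def test_filter_bins_catches_simulated_overrepresentation(small_binning):
    # low depth so only the deliberately spiked bins cross the 1000 mark
    cfg = SimulationConfig(frac_overrepresented=0.25, p_qc_fail=0.0, depth=5_000)
    config = ChromatidConfiguration(
        "p1", "control", {c.name: (2, 2) for c in small_binning.chromosomes}
    )
    (egg, _), = simulate_read_counts([config], small_binning, cfg, seed=3)
    n_forced = int(round(0.25 * small_binning.n_bins))
    mask = filter_bins(egg)
    assert len(mask) >= n_forced
    assert all(egg.counts[i] > 1000 for i in mask)


# --- normalization --------------------------------------------------------


def test_normalize_scale_factor(small_binning):
    n_auto = sum(small_binning.autosome_mask())
    sample = _sample(small_binning, fill=2_000_000 / n_auto)
    norm = normalize(sample, small_binning)
    auto = np.asarray(small_binning.autosome_mask())
    assert np.nansum(norm[auto]) == pytest.approx(1_000_000, rel=1e-9)
    # scale was 0.5
    assert norm[0] == pytest.approx(sample.counts[0] * 0.5)


def test_normalize_is_idempotent(small_binning):
    rng = np.random.default_rng(0)
    sample = BinnedCounts("s", rng.integers(50, 500, small_binning.n_bins))
    once = normalize(sample, small_binning)
    twice = normalize(BinnedCounts("s", once), small_binning)
    np.testing.assert_allclose(twice, once, rtol=1e-12)


def test_normalize_applies_same_factor_to_sex_bins(small_binning):
    sample = _sample(small_binning, fill=500.0)
    norm = normalize(sample, small_binning)
    # uniform input stays uniform: X bins equal autosome bins post-scaling
    assert np.nanstd(norm) < 1e-6 * np.nanmean(norm)


def test_normalize_zero_autosomal_total_errors(small_binning):
    counts = np.zeros(small_binning.n_bins)
    x_bins = small_binning.bin_indices("X")
    counts[x_bins] = 100.0  # signal only on X
    with pytest.raises(NormalizationError):
        normalize(BinnedCounts("s", counts), small_binning)


def test_fold_change_scale_invariance(small_binning):
    """Multiplying all raw counts by a constant changes no fold change."""
    rng = np.random.default_rng(1)
    counts = rng.integers(50, 900, small_binning.n_bins).astype(float)
    panel = rng.integers(50, 900, small_binning.n_bins).astype(float)
    panel_norm = normalize(BinnedCounts("p", panel), small_binning)
    fc1, _ = fold_change(
        normalize(BinnedCounts("s", counts), small_binning), panel_norm
    )
    fc2, _ = fold_change(
        normalize(BinnedCounts("s", counts * 7.3), small_binning), panel_norm
    )
    np.testing.assert_allclose(fc2, fc1, rtol=1e-12)


# --- fold change and observed copy number ---------------------------------


def test_fold_change_identity(small_binning):
    rng = np.random.default_rng(2)
    counts = rng.integers(50, 900, small_binning.n_bins).astype(float)
    norm = normalize(BinnedCounts("s", counts), small_binning)
    fc, excl = fold_change(norm, norm.copy())
    np.testing.assert_allclose(fc, 1.0)
    assert excl == {}


def test_fold_change_masks_zero_panel_bins(small_binning):
    counts = np.full(small_binning.n_bins, 100.0)
    norm = normalize(BinnedCounts("s", counts), small_binning)
    panel = norm.copy()
    panel[3] = 0.0
    fc, excl = fold_change(norm, panel)
    assert np.isnan(fc[3])
    assert excl == {3: "zero-panel"}


def test_observed_cn_doubles_autosomal_fold_change(small_binning):
    fc = np.full(small_binning.n_bins, 1.0)
    fc[small_binning.bin_indices("1")] = 2.0  # 4 chromatids of chr 1
    fc[small_binning.bin_indices("X")] = 2.0  # 2 chromatids vs 1-copy panel
    cn, undefined = observed_cn(fc, small_binning)
    assert cn["1"] == pytest.approx(4.0)
    assert cn["2"] == pytest.approx(2.0)
    assert cn["X"] == pytest.approx(2.0)  # sex chromosome: x1, not x2
    assert undefined == ()


def test_observed_cn_uses_median_of_bins(small_binning):
    fc = np.full(small_binning.n_bins, 1.0)
    idx = small_binning.bin_indices("2")
    fc[idx[:3]] = [0.9, 1.0, 1.1]
    cn, _ = observed_cn(fc, small_binning)
    assert cn["2"] == pytest.approx(2.0)


def test_observed_cn_flags_fully_masked_chromosome(small_binning):
    fc = np.full(small_binning.n_bins, 1.0)
    fc[small_binning.bin_indices("2")] = np.nan
    cn, undefined = observed_cn(fc, small_binning)
    assert "2" not in cn
    assert undefined == ("2",)


# --- noiseless pipeline properties ----------------------------------------


def test_noiseless_panel_x_bins_half_of_autosomes(small_binning):
    cfg = SimulationConfig(nb_size=None, bias_sigma=0.0)
    panel, truth = simulate_normal_panel(small_binning, cfg, seed=0)
    assert set(truth) == {c.name for c in small_binning.chromosomes}
    # per-bp rate on X is half the autosomal rate (1 copy vs 2)
    def rate(chrom):
        idx = small_binning.bin_indices(chrom)
        widths = [small_binning.bins[i][2] - small_binning.bins[i][1] for i in idx]
        return panel.counts[idx[0]] / widths[0]
    assert rate("X") == pytest.approx(rate("1") / 2)


def test_panel_truth_covers_all_chromosomes():
    binning = make_binning()
    cfg = SimulationConfig(nb_size=None, bias_sigma=0.0)
    _, truth = simulate_normal_panel(binning, cfg, seed=0)
    assert len(truth) == 21
    assert truth["X"] == 1.0 and truth["Y"] == 1.0 and truth["7"] == 2.0


def test_panel_averaging_converges_to_noiseless(small_binning):
    """Mean of k noisy panels approaches the noiseless panel ~ 1/sqrt(k)."""
    cfg_noisy = SimulationConfig(nb_size=20.0, bias_sigma=0.0, depth=5_000)
    cfg_clean = SimulationConfig(nb_size=None, bias_sigma=0.0, depth=5_000)
    clean, _ = simulate_normal_panel(small_binning, cfg_clean, seed=0)
    clean_norm = build_panel([clean], small_binning)
    rng = np.random.default_rng(5)

    def mean_error(k):
        panels = [
            simulate_normal_panel(small_binning, cfg_noisy, rng)[0] for _ in range(k)
        ]
        avg = build_panel(panels, small_binning)
        return float(np.nanmean(np.abs(avg - clean_norm) / clean_norm))

    few, many = mean_error(4), mean_error(64)
    assert many < few / 2  # expected ratio 1/4 with slack for Monte Carlo


def test_noiseless_roundtrip_recovers_truth_exactly(noiseless_study):
    """Zero dispersion, no masking: observed_cn equals true chromatid count.

    Within-sample normalization only identifies counts up to a per-sample
    scale, so compare ratios: observed / truth must be constant per sample.
    """
    for index in (0, 15, 30):
        truth = noiseless_study.configurations[index]
        for obs, side in zip(observed_pair(noiseless_study, index), (0, 1)):
            ratios = [
                obs[c] / truth.counts[c][side]
                for c in truth.counts
                if truth.counts[c][side] > 0
            ]
            assert max(ratios) - min(ratios) < 1e-9
            # chromosomes absent from the sample read out as ~0 copies
            for c in truth.counts:
                if truth.counts[c][side] == 0:
                    assert obs[c] == pytest.approx(0.0, abs=1e-9)
    # a euploid control pair has scale exactly 1: equality with truth
    truth = noiseless_study.configurations[0]
    assert all(v == (2, 2) for v in truth.counts.values())
    ep, pp = observed_pair(noiseless_study, 0)
    for chrom in truth.counts:
        assert ep[chrom] == pytest.approx(2.0, abs=1e-9)
        assert pp[chrom] == pytest.approx(2.0, abs=1e-9)


def test_monotonicity_of_observed_cn(small_binning):
    """More chromatids on one chromosome: its observed copies rise, the
    others weakly fall through the shared normalization denominator."""
    cfg = SimulationConfig(nb_size=None, bias_sigma=0.0, p_qc_fail=0.0, depth=5_000)
    chroms = [c.name for c in small_binning.chromosomes]
    panel, _ = simulate_normal_panel(small_binning, cfg, seed=0)
    panel_norm = build_panel([panel], small_binning)

    def observed(egg_counts):
        config = ChromatidConfiguration(
            "p", "g", {c: (egg_counts.get(c, 2), 4 - egg_counts.get(c, 2)) for c in chroms}
        )
        (egg, _), = simulate_read_counts([config], small_binning, cfg, seed=0)
        return call_profile(egg, panel_norm, small_binning).observed_cn

    base = observed({})
    more = observed({"1": 3})
    even_more = observed({"1": 4})
    assert base["1"] < more["1"] < even_more["1"]
    assert more["2"] <= base["2"] and even_more["2"] <= more["2"]


# --- on-disk format -------------------------------------------------------


def test_counts_tsv_roundtrip(tmp_path, small_binning):
    rng = np.random.default_rng(3)
    sample = BinnedCounts(
        "egg_01",
        rng.integers(0, 800, small_binning.n_bins),
        mapped_fraction=0.97,
        sample_role="egg",
    )
    path = tmp_path / "egg_01.tsv"
    write_counts_tsv(sample, small_binning, path)
    back = read_counts_tsv(path, small_binning)
    np.testing.assert_array_equal(back.counts, sample.counts)
    assert back.sample_id == "egg_01"
    assert back.mapped_fraction == 0.97
    assert back.sample_role == "egg"


def test_counts_tsv_rejects_wrong_binning(tmp_path, small_binning):
    sample = BinnedCounts("s", np.zeros(small_binning.n_bins))
    path = tmp_path / "s.tsv"
    write_counts_tsv(sample, small_binning, path)
    other = make_binning(small_binning.chromosomes, window_size=5_000_000)
    with pytest.raises(ValueError, match="do not match"):
        read_counts_tsv(path, other)
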