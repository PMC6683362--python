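"""Synthetic-cohort generator: determinism, depth laws, dosage structure."""

import numpy as np
import pytest

from hybridogen.errors import ConfigurationError
from hybridogen.simulate import (
    DOSAGE_P_L,
    MicrosatLocus,
    PeakSimConfig,
    SimConfig,
    planted_panel,
    simulate_cohort,
    simulate_peak_table,
)


def _all_depth_fracs(gm, panel_df, cls_prefix):
    """Empirical L-allele depth fraction pooled over all diagnostic cells."""
    d_l = d_tot = 0
    lookup = dict(zip(panel_df["locus"], zip(panel_df["l_allele"], panel_df["r_allele"])))
    for s in gm.sample_ids:
        if not s.startswith(cls_prefix):
            continue
        for locus, (la, ra) in lookup.items():
            dd = gm.depths_at(s, locus)
            if dd is None:
                continue
            d_l += dd[la]
            d_tot += dd[la] + dd[ra]
    return d_l / d_tot


def test_same_seed_same_cohort_distinct_seeds_differ():
    cfg = SimConfig(n_per_class={"LR": 3}, n_loci_total=40, n_diagnostic=10, seed=5)
    gm1, _, _ = simulate_cohort(cfg)
    gm2, _, _ = simulate_cohort(cfg)
    assert gm1._genotypes == gm2._genotypes
    assert gm1._depths == gm2._depths
    gm3, _, _ = simulate_cohort(
        SimConfig(n_per_class={"LR": 3}, n_loci_total=40, n_diagnostic=10, seed=6)
    )
    assert gm1._depths != gm3._depths


def test_diploid_depths_concentrate_at_half_at_high_depth():
    """At depth 1000 with no error, both alleles of every diagnostic cell
    of an LR diploid land within [400, 600] reads (binomial concentration)."""
    cfg = SimConfig(
        n_per_class={"LR": 5},
        n_loci_total=30,
        n_diagnostic=30,
        depth_mean=1000.0,
        depth_dispersion="poisson",
        seq_error=0.0,
        missing_rate=0.0,
        seed=7,
    )
    gm, _, _ = simulate_cohort(cfg)
    for s in gm.sample_ids:
        for locus in gm.locus_ids:
            dd = gm.depths_at(s, locus)
            for d in dd.values():
                assert 400 <= d <= 600


@pytest.mark.parametrize("cls", ["LR", "LLR", "LRR"])
def test_depth_fractions_converge_to_dosage_proportions(cls):
    """Law of large numbers: pooled L-read fraction approaches the genome
    dosage (1/2, 2/3, 1/3) at depth 1e4."""
    cfg = SimConfig(
        n_per_class={cls: 3},
        n_loci_total=50,
        n_diagnostic=50,
        depth_mean=1e4,
        depth_dispersion="poisson",
        seq_error=0.0,
        missing_rate=0.0,
        seed=13,
    )
    gm, _, _ = simulate_cohort(cfg)
    frac = _all_depth_fracs(gm, planted_panel(cfg), cls)
    assert frac == pytest.approx(DOSAGE_P_L[cls], abs=0.01)


def test_pure_ll_has_zero_r_depth_without_error():
    cfg = SimConfig(
        n_per_class={"LL": 4}, n_loci_total=40, n_diagnostic=20,
        seq_error=0.0, missing_rate=0.0, seed=2,
    )
    gm, _, _ = simulate_cohort(cfg)
    panel = planted_panel(cfg)
    for s in gm.sample_ids:
        for locus, ra in zip(panel["locus"], panel["r_allele"]):
            assert gm.depths_at(s, locus)[ra] == 0


def test_hemiclonal_rr_far_less_heterozygous_than_hybrids():
    """The study's contrast: hemiclonal RR show near-zero heterozygosity,
    hybrids are heterozygous at every diagnostic locus and then some."""
    cfg = SimConfig(
        n_per_class={"RR": 5, "LR": 5},
        n_loci_total=400,
        n_diagnostic=100,
        residual_het=0.01,
        missing_rate=0.0,
        seed=21,
    )
    gm, _, _ = simulate_cohort(cfg)

    def group_het(prefix):
        vals = []
        for s in gm.sample_ids:
            if not s.startswith(prefix):
                continue
            hets = [gm.is_het(s, l) for l in gm.locus_ids]
            vals.append(np.mean([h for h in hets if h is not None]))
        return float(np.mean(vals))

    assert group_het("RR") < 0.05 < group_het("LR")


def test_missing_rate_controls_missingness():
    cfg = SimConfig(
        n_per_class={"LR": 10}, n_loci_total=300, n_diagnostic=50,
        missing_rate=0.2, seed=9,
    )
    gm, _, _ = simulate_cohort(cfg)
    miss = np.mean([
        gm.genotype(s, l) is None for s in gm.sample_ids for l in gm.locus_ids
    ])
    assert miss == pytest.approx(0.2, abs=0.03)


def test_config_validation():
    with pytest.raises(ConfigurationError):
        SimConfig(n_per_class={"LL": 0})
    with pytest.raises(ConfigurationError):
        SimConfig(n_diagnostic=100, n_loci_total=50)
    with pytest.raises(ConfigurationError):
        SimConfig(seq_error=0.6)
    with pytest.raises(ConfigurationError):
        PeakSimConfig(sigma=-1.0)


# -- peak simulation --------------------------------------------------------

def _heights(pt, sample, locus):
    df = pt.peaks_for(sample, locus)
    return dict(zip(df["allele"], df["height"]))


def test_peak_heights_proportional_to_copy_number():
    """With unit efficiencies and no noise: LR peaks are equal and the
    duplicated genome of an LRR frog doubles its peak."""
    locus = MicrosatLocus("ms1", l_alleles=(122,), r_alleles=(137,))
    cfg = PeakSimConfig(
        n_per_class={"LR": 1, "LRR": 1}, loci=(locus,), sigma=0.0, seed=0
    )
    pt, _ = simulate_peak_table(cfg)
    lr = _heights(pt, "LR_000", "ms1")
    assert lr[122] == lr[137] == 1000.0
    lrr = _heights(pt, "LRR_000", "ms1")
    assert lrr[137] == 2 * lrr[122]


def test_llr_with_distinct_l_alleles_is_triallelic():
    locus = MicrosatLocus("ms1", l_alleles=(122, 123), r_alleles=(137,))
    cfg = PeakSimConfig(n_per_class={"LLR": 40}, loci=(locus,), sigma=0.0, seed=3)
    pt, _ = simulate_peak_table(cfg)
    n_peaks = pt.records.groupby("sample")["allele"].nunique()
    assert (n_peaks == 3).any()  # some frogs drew two distinct L alleles
    tri = n_peaks[n_peaks == 3].index
    for s in tri:
        h = _heights(pt, s, "ms1")
        assert h[137] == 1000.0 and h[122] == h[123] == 1000.0


def test_null_alleles_emit_no_record():
    locus = MicrosatLocus("ms1", l_alleles=(122,), r_alleles=(137,))
    cfg = PeakSimConfig(n_per_class={"LR": 200}, loci=(locus,), sigma=0.0,
                        null_prob=0.3, seed=4)
    pt, _ = simulate_peak_table(cfg)
    # 2 alleles x 200 samples, each kept w.p. 0.7
    assert len(pt) == pytest.approx(280, abs=40)
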