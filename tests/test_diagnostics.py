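"""Diagnostic-locus discovery against an independent brute-force oracle."""

import numpy as np
import pytest

from hybridogen.diagnostics import find_diagnostic_loci, panel_coverage_report
from hybridogen.errors import ConfigurationError
from hybridogen.io import GenotypeMatrix, PopAssignment, PopulationMap, TaxonHint
from hybridogen.simulate import SimConfig, planted_panel, simulate_cohort


def brute_force_panel(gm, pm, min_ref_called=3, require_biallelic=True):
    """Independent oracle: per locus, compute allele frequencies in each
    reference group and demand an allele-frequency difference of 1.0
    (one allele at frequency 1 in LL refs and 0 in RR refs, another the
    reverse)."""
    ll = [s for s in pm.samples_with_hint(TaxonHint.LL_REF) if s in gm.sample_ids]
    rr = [s for s in pm.samples_with_hint(TaxonHint.RR_REF) if s in gm.sample_ids]
    out = {}
    for locus in gm.locus_ids:
        if require_biallelic and len(gm.alleles.get(locus, ())) != 2:
            continue

        def freqs(group):
            counts = {}
            n = 0
            called = 0
            for s in group:
                call = gm.genotype(s, locus)
                if call is None:
                    continue
                called += 1
                for a in call:
                    counts[a] = counts.get(a, 0) + 1
                    n += 1
            return ({a: c / n for a, c in counts.items()} if n else {}), called

        f_ll, n_ll = freqs(ll)
        f_rr, n_rr = freqs(rr)
        if n_ll < min_ref_called or n_rr < min_ref_called:
            continue
        fixed = [
            (a, b)
            for a in f_ll
            for b in f_rr
            if a != b
            and f_ll[a] == 1.0
            and f_rr.get(a, 0.0) == 0.0
            and f_rr[b] == 1.0
            and f_ll.get(b, 0.0) == 0.0
        ]
        if fixed:
            (a, b), = fixed
            out[locus] = (a, b)
    return out


def random_matrix(rng, n_samples, n_loci):
    """Random small matrix with random reference labels and missingness."""
    samples = [f"S{i}" for i in range(n_samples)]
    loci = [f"c{j}:1" for j in range(n_loci)]
    alleles = {}
    genotypes = {s: {} for s in samples}
    for l in loci:
        k = rng.choice([2, 2, 2, 3])  # mostly biallelic
        site = tuple(rng.choice(list("ACGT"), size=k, replace=False))
        alleles[l] = site
        for s in samples:
            if rng.random() < 0.15:
                continue
            # skew towards homozygous calls so fixation actually happens
            if rng.random() < 0.7:
                a = site[rng.integers(0, min(2, k))]
                genotypes[s][l] = (a, a)
            else:
                i, j = rng.integers(0, k, size=2)
                genotypes[s][l] = (site[i], site[j])
    hints = [TaxonHint.LL_REF, TaxonHint.RR_REF] + [
        rng.choice([TaxonHint.LL_REF, TaxonHint.RR_REF, TaxonHint.UNKNOWN])
        for _ in range(n_samples - 2)
    ]
    pm = PopulationMap({s: PopAssignment("p", h) for s, h in zip(samples, hints)})
    return GenotypeMatrix(samples, loci, alleles, genotypes), pm


@pytest.mark.parametrize("batch", range(4))
def test_discovery_matches_brute_force_on_random_matrices(batch):
    """find_diagnostic_loci set-equals the allele-frequency oracle on 200
    random matrices (50 per batch), including orientation."""
    rng = np.random.default_rng(100 + batch)
    for _ in range(50):
        gm, pm = random_matrix(
            rng, n_samples=int(rng.integers(6, 21)), n_loci=int(rng.integers(5, 101))
        )
        expected = brute_force_panel(gm, pm)
        panel = find_diagnostic_loci(gm, pm)
        got = {e.locus_id: (e.l_allele, e.r_allele) for e in panel}
        assert got == expected


def test_min_ref_called_monotonicity():
    """Raising the reference-call floor never adds a locus."""
    rng = np.random.default_rng(42)
    gm, pm = random_matrix(rng, 12, 60)
    panels = [
        set(find_diagnostic_loci(gm, pm, min_ref_called=m).loci()) for m in (1, 2, 3, 4, 5)
    ]
    for small, large in zip(panels[1:], panels):
        assert small <= large


def test_planted_panel_recovered_exactly_without_noise():
    cfg = SimConfig(
        n_per_class={"LL": 6, "RR": 6, "LR": 10},
        n_loci_total=150,
        n_diagnostic=60,
        seq_error=0.0,
        missing_rate=0.0,
        seed=31,
    )
    gm, pm, _ = simulate_cohort(cfg)
    panel = find_diagnostic_loci(gm, pm)
    planted = planted_panel(cfg)
    assert set(panel.loci()) == set(planted["locus"])
    oriented = {e.locus_id: (e.l_allele, e.r_allele) for e in panel}
    for row in planted.itertuples(index=False):
        assert oriented[row.locus] == (row.l_allele, row.r_allele)


def test_discovery_requires_both_reference_groups():
    rng = np.random.default_rng(1)
    gm, _ = random_matrix(rng, 8, 10)
    pm = PopulationMap(
        {s: PopAssignment("p", TaxonHint.LL_REF) for s in gm.sample_ids}
    )
    with pytest.raises(ConfigurationError, match="RR_REF"):
        find_diagnostic_loci(gm, pm)


def test_panel_coverage_counts(small_cohort, small_panel):
    """Complete matrix: every sample covers the whole panel with depths
    at diagnostic loci."""
    _, gm, _, _ = small_cohort
    report = panel_coverage_report(gm, small_panel)
    assert (report["n_called"] == len(small_panel)).all()
    assert (report["n_with_depths"] == len(small_panel)).all()


def test_panel_coverage_tracks_missingness():
    cfg = SimConfig(
        n_per_class={"LL": 5, "RR": 5, "LR": 10},
        n_loci_total=300,
        n_diagnostic=150,
        missing_rate=0.2,
        seq_error=0.0,
        seed=17,
    )
    gm, pm, _ = simulate_cohort(cfg)
    panel = find_diagnostic_loci(gm, pm, min_ref_called=2)
    report = panel_coverage_report(gm, panel)
    assert report["n_called"].mean() == pytest.approx(0.8 * len(panel), rel=0.05)
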