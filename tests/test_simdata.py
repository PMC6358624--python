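"""Synthetic-panel generator: determinism, drift structure, pulse truth."""

import numpy as np
import pytest
from scipy.stats import kstest

from coanpipe import apply_admixture_pulse, simulate_structured_panel
from coanpipe.simdata import (
    DemeSpec,
    DemographicScenario,
    DonorSpec,
    GenomeSpec,
    PulseSpec,
    assign_geography,
    simulate_drift_admixture_scenario,
)


def _scenario(**kw):
    base = dict(
        demes=[DemeSpec("A", 10, drift=0.1)],
        genome=GenomeSpec(2, 60.0, 50),
        seed=0,
    )
    base.update(kw)
    return DemographicScenario(**base)


def test_same_seed_is_byte_identical():
    sc = _scenario(
        demes=[DemeSpec("A", 8, drift=0.2), DemeSpec("B", 8, drift=0.1)],
        pulses=[PulseSpec("B", "A", 0.3, 10)],
    )
    p1, t1 = simulate_structured_panel(sc)
    p2, t2 = simulate_structured_panel(sc)
    assert np.array_equal(p1.haplotypes, p2.haplotypes)
    assert t1.tracts.equals(t2.tracts)


def test_no_structure_case_identity_uniform():
    sc = _scenario(demes=[DemeSpec("A", 20, drift=0.0)], genome=GenomeSpec(2, 60, 200))
    panel, _ = simulate_structured_panel(sc)
    H = panel.haplotypes
    # all pairwise identities statistically indistinguishable: compare the
    # spread of pairwise identity to binomial sampling noise
    ident = 1 - np.abs(H[:, None, :] - H[None, :, :]).mean(axis=2)
    iu = np.triu_indices(H.shape[0], k=1)
    vals = ident[iu]
    assert vals.std() < 3 * np.sqrt(0.5 * 0.5 / H.shape[1])


def test_drifted_demes_have_excess_within_identity():
    sc = _scenario(
        demes=[DemeSpec("A", 20, drift=0.2), DemeSpec("B", 20, drift=0.2)],
        genome=GenomeSpec(2, 60, 200),
    )
    panel, _ = simulate_structured_panel(sc)
    H = panel.haplotypes
    a, b = H[:40], H[40:]
    within = (
        (1 - np.abs(a[:, None] - a[None, :]).mean(2)).mean()
        + (1 - np.abs(b[:, None] - b[None, :]).mean(2)).mean()
    ) / 2
    between = (1 - np.abs(a[:, None] - b[None, :]).mean(2)).mean()
    assert within > between


@pytest.mark.parametrize(
    "bad,field",
    [
        (dict(demes=[DemeSpec("A", 1)]), "n"),
        (dict(demes=[DemeSpec("A", 5, drift=1.5)]), "drift"),
        (
            dict(
                demes=[DemeSpec("A", 5)],
                pulses=[PulseSpec("base", "A", 1.2, 5)],
            ),
            "alpha",
        ),
        (
            dict(
                demes=[DemeSpec("A", 5)],
                pulses=[PulseSpec("base", "A", 0.5, 0)],
            ),
            "g",
        ),
        (
            dict(
                demes=[DemeSpec("A", 5)],
                pulses=[PulseSpec("nowhere", "A", 0.5, 5)],
            ),
            "source",
        ),
    ],
)
def test_validation_errors_name_the_field(bad, field):
    with pytest.raises(ValueError, match=field):
        simulate_structured_panel(_scenario(**bad))


def test_null_pulse_leaves_panel_unchanged():
    sc = _scenario(demes=[DemeSpec("A", 6)], donors=[DonorSpec("S", 4)])
    panel, truth = simulate_structured_panel(sc)
    panel2, truth2 = apply_admixture_pulse(panel, truth, "S", "A", 0.0, 10, seed=1)
    assert np.array_equal(panel.haplotypes, panel2.haplotypes)
    a_ids = [i for i in panel.ids if i.startswith("A")]
    t = truth2.tracts[truth2.tracts["id"].isin(a_ids)]
    assert not (t["source"] == "S").any()


def test_full_replacement_pulse():
    sc = _scenario(demes=[DemeSpec("A", 6)], donors=[DonorSpec("S", 4)])
    panel, truth = simulate_structured_panel(sc)
    _, truth2 = apply_admixture_pulse(panel, truth, "S", "A", 1.0, 10, seed=1)
    a_ids = [i for i in panel.ids if i.startswith("A")]
    t = truth2.tracts[truth2.tracts["id"].isin(a_ids)]
    assert (t["source"] == "S").all()


def test_tracts_tile_chromosomes():
    sc = _scenario(
        demes=[DemeSpec("A", 10)],
        donors=[DonorSpec("S", 4)],
        pulses=[PulseSpec("S", "A", 0.3, 20)],
    )
    panel, truth = simulate_structured_panel(sc)
    assert truth.check_tiling(panel.gmap)


def test_realized_alpha_converges():
    """Law-of-large-numbers check at n = 200 individuals, 3 SE tolerance."""
    sc = DemographicScenario(
        demes=[DemeSpec("A", 200)],
        donors=[DonorSpec("S", 2)],
        pulses=[PulseSpec("S", "A", 0.25, 20)],
        genome=GenomeSpec(2, 100, 20),
        seed=5,
    )
    panel, truth = simulate_structured_panel(sc)
    realized = truth.realized_alpha("A", "S")
    # per-haplotype genome share has variance ~ alpha(1-alpha)/n_segments
    n_seg = 400 * 2 * 20  # haps x chroms x E[segments per chrom]
    se = np.sqrt(0.25 * 0.75 / n_seg)
    assert abs(realized - 0.25) < 3 * se + 0.01


def test_tract_lengths_exponential():
    """Complete renewal segments are Exp(100/g) cM (KS at n >= 1000)."""
    g = 30
    sc = DemographicScenario(
        demes=[DemeSpec("A", 30)],
        donors=[DonorSpec("S", 2)],
        pulses=[PulseSpec("S", "A", 0.5, g)],
        genome=GenomeSpec(4, 100, 12),
        seed=7,
    )
    panel, truth = simulate_structured_panel(sc)
    a_ids = [i for i in panel.ids if i.startswith("A")]
    lengths = truth.tract_lengths(complete_only=True)
    t = truth.tracts
    last = t.groupby(["hap", "chrom"])["end_cm"].transform("max")
    lengths = (t[(t["end_cm"] < last) & t["id"].isin(a_ids)]
               .eval("end_cm - start_cm").to_numpy())
    assert len(lengths) >= 1000
    assert abs(lengths.mean() - 100 / g) / (100 / g) < 0.1
    assert kstest(lengths, "expon", args=(0, 100 / g)).pvalue > 0.01


@pytest.mark.parametrize(
    "which", ["split", "mix-into-alpha", "mix-into-beta-from-drifted", "bidirectional"]
)
def test_drift_admixture_scenarios_deterministic(which):
    p1, t1 = simulate_drift_admixture_scenario(which, seed=2)
    p2, t2 = simulate_drift_admixture_scenario(which, seed=2)
    assert np.array_equal(p1.haplotypes, p2.haplotypes)
    assert set(p1.metadata["group"]) == {"alpha", "beta", "bg1", "bg2"}
    assert t1.check_tiling(p1.gmap)


def test_drift_admixture_scenario_unknown_name():
    with pytest.raises(ValueError, match="unknown scenario"):
        simulate_drift_admixture_scenario("not-a-scenario", seed=0)


def test_geography_zero_dispersion_and_distant_fraction():
    sc = _scenario(
        demes=[DemeSpec("A", 100, centroid=(10.0, -5.0), dispersion_km=0.0)]
    )
    panel, _ = simulate_structured_panel(sc)
    meta = assign_geography(panel, sc, seed=3)
    for k in range(1, 5):
        assert (meta[f"gp{k}_x"] == 10.0).all()
        assert (meta[f"gp{k}_y"] == -5.0).all()
    # distant-grandparent fraction ~ binomial count
    meta2 = assign_geography(panel, sc, seed=3, distant_fraction=0.2, distant_km=150)
    d4 = np.hypot(meta2["gp4_x"] - 10.0, meta2["gp4_y"] + 5.0)
    n_far = int((d4 > 100).sum())
    assert 8 <= n_far <= 34  # ~Binomial(100, 0.2) within ~3 SD


def test_geography_dispersion_rms():
    sc = _scenario(demes=[DemeSpec("A", 150, dispersion_km=5.0)])
    panel, _ = simulate_structured_panel(sc)
    meta = assign_geography(panel, sc, seed=4)
    d2 = np.concatenate(
        [
            meta[f"gp{k}_x"] ** 2 + meta[f"gp{k}_y"] ** 2
            for k in range(1, 5)
        ]
    )
    rms = np.sqrt(d2.mean())
    assert abs(rms - 5.0 * np.sqrt(2)) / (5.0 * np.sqrt(2)) < 0.15
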