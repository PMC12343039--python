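"""Synthetic ledger generator: selectivity, scarcity shift, recovery."""

import numpy as np
import pytest

from loricaballast import (
    AmbientAssemblage,
    AmbientParticle,
    CaptureModel,
    SimulationParams,
    capture_weights,
    default_assemblage,
    effective_abundances,
    estimate_dataset,
    expected_mean_ballast,
    read_ledger,
    recovery_experiment,
    simulate_dataset,
    write_ledger,
)


def test_strength_zero_recovers_ambient_proportions():
    ab = [0.5, 0.3, 0.2]
    w = capture_weights([3, 8, 15], 40.0, CaptureModel(selectivity_strength=0.0), ab)
    assert w == pytest.approx(ab)


def test_two_particle_window_boost():
    """Equal abundance, one particle inside the window, strength 1 → (2/3, 1/3)."""
    model = CaptureModel(selectivity_window=(0.2, 0.3), selectivity_strength=1.0)
    w = capture_weights([10, 2], 40.0, model)  # 10/40 = 0.25 inside, 2/40 outside
    assert w == pytest.approx([2 / 3, 1 / 3])


def test_large_lorica_upweights_heavy_liths():
    """At D = 40 μm the 8–12 μm liths (Calcidiscus/Helicosphaera scale) gain."""
    model = CaptureModel(selectivity_window=(0.2, 0.3), selectivity_strength=2.0)
    sizes = [3.5, 9.0, 12.0, 15.0]
    w = capture_weights(sizes, 40.0, model)
    w0 = capture_weights(sizes, 40.0, CaptureModel(selectivity_strength=0.0))
    assert w[1] > w0[1] and w[2] > w0[2]
    assert w[0] < w0[0] and w[3] < w0[3]


def test_in_window_share_monotone_in_strength():
    sizes = [3.5, 9.0, 15.0]
    shares = []
    for strength in [0.0, 0.5, 1.0, 2.0, 5.0]:
        w = capture_weights(sizes, 40.0, CaptureModel(selectivity_strength=strength))
        shares.append(w[1])  # 9/40 = 0.225 is in-window
    assert all(b >= a for a, b in zip(shares, shares[1:]))


def test_degenerate_ambient_rejected():
    with pytest.raises(ValueError, match="degenerate"):
        AmbientAssemblage(
            region_class="polar",
            pool=(AmbientParticle("Emiliania", "coccolith", 0.0, 3.5),),
        )


def test_scarcity_shift_removes_coccoliths():
    ambient = default_assemblage("polar", coccolith_availability=0.0)
    model = CaptureModel(scarcity_threshold=0.5)
    ab = effective_abundances(ambient, model)
    for particle, a in zip(ambient.pool, ab):
        if particle.particle_kind == "coccolith":
            assert a == 0.0
    assert ab.sum() == pytest.approx(1.0)


def test_availability_above_threshold_no_shift():
    ambient = default_assemblage("polar", coccolith_availability=0.8)
    model = CaptureModel(scarcity_threshold=0.5)
    ab = effective_abundances(ambient, model)
    assert ab == pytest.approx([p.rel_abundance for p in ambient.pool])


def test_seeded_determinism(tmp_path):
    params = SimulationParams(n_loricae=30, seed=11)
    d1 = simulate_dataset(params)
    d2 = simulate_dataset(params)
    assert d1.loricae == d2.loricae and d1.observations == d2.observations
    write_ledger(d1, tmp_path / "a")
    write_ledger(d2, tmp_path / "b")
    assert (tmp_path / "a/observations.csv").read_bytes() == (
        tmp_path / "b/observations.csv"
    ).read_bytes()
    d3 = simulate_dataset(SimulationParams(n_loricae=30, seed=12))
    assert d3.observations != d1.observations


def test_pure_emiliania_ambient():
    ambient = AmbientAssemblage(
        region_class="polar",
        pool=(AmbientParticle("Emiliania", "coccolith", 1.0, 3.5),),
    )
    ds = simulate_dataset(SimulationParams(n_loricae=20, seed=3, ambient=ambient))
    assert {o.particle_taxon for o in ds.observations} == {"Emiliania"}


def test_simulated_dataset_round_trips_and_validates(tmp_path):
    ds = simulate_dataset(SimulationParams(n_loricae=25, seed=5))
    ds.validate_integrity()
    write_ledger(ds, tmp_path / "sim")
    back = read_ledger(tmp_path / "sim", ds.reference)
    assert back.loricae == ds.loricae and back.observations == ds.observations


def test_scarcity_drives_silica_fraction_to_one():
    ambient = default_assemblage("polar", coccolith_availability=0.0)
    params = SimulationParams(
        n_loricae=500, seed=17, ambient=ambient,
        capture=CaptureModel(scarcity_threshold=0.5),
    )
    ds = simulate_dataset(params)
    estimates = estimate_dataset(ds)
    caco3 = sum(e.caco3_total for e in estimates.values())
    total = sum(e.total for e in estimates.values())
    assert caco3 == 0.0
    assert total > 0


def test_nonselective_capture_converges_to_ambient():
    """Captured-taxon frequencies approach the ambient composition:
    total-variation distance < 3·sqrt(Σ p(1−p) / N) for N particles."""
    ambient = default_assemblage("temperate")
    params = SimulationParams(
        n_loricae=200, seed=23, ambient=ambient,
        oral_diameter_mean=22.0,
        capture=CaptureModel(selectivity_strength=0.0, particles_per_lorica=100),
    )
    ds = simulate_dataset(params)
    ref = ds.reference
    counts: dict[str, float] = {}
    for o in ds.observations:
        if o.quantity_type == "count":
            n = o.quantity
        else:  # biovolume accumulations: back out the particle count
            kind = "whole_cell" if o.particle_kind == "diatom_cell" else "fragment"
            n = o.quantity / ref.resolve_diatom(o.particle_taxon, kind).biovolume
        counts[o.particle_taxon] = counts.get(o.particle_taxon, 0.0) + n
    n_total = sum(counts.values())
    p = {pt.taxon: pt.rel_abundance for pt in ambient.pool}
    tv = 0.5 * sum(abs(counts.get(t, 0) / n_total - p[t]) for t in p)
    bound = 3 * np.sqrt(sum(v * (1 - v) for v in p.values()) / n_total)
    assert tv < bound


def test_recovery_emiliania_only():
    """100 liths/lorica of 4 pg liths → E[B] = 400 pg; estimate within 3 SE."""
    ambient = AmbientAssemblage(
        region_class="polar",
        pool=(AmbientParticle("Emiliania", "coccolith", 1.0, 3.5),),
    )
    params = SimulationParams(
        n_loricae=200, seed=31, ambient=ambient,
        capture=CaptureModel(selectivity_strength=0.0, particles_per_lorica=100),
    )
    assert expected_mean_ballast(params) == pytest.approx(400.0)
    rep = recovery_experiment(params)
    assert rep.expected_mean_total == pytest.approx(400.0)
    assert abs(rep.z_total) < 3


def test_recovery_mixed_ambient_is_calibrated():
    """z-scores behave like standard normal draws across independent seeds
    (mean |z| well below 1.5), and mass shares track the analytic ones."""
    zs = []
    for seed in range(5):
        params = SimulationParams(
            n_loricae=200, seed=seed, ambient=default_assemblage("temperate"),
            capture=CaptureModel(selectivity_strength=0.0, particles_per_lorica=120),
        )
        rep = recovery_experiment(params)
        zs.append(abs(rep.z_total))
        assert rep.observed_share.keys() == rep.expected_share.keys()
        for taxon, share in rep.expected_share.items():
            assert rep.observed_share[taxon] == pytest.approx(share, abs=0.05)
    assert np.mean(zs) < 1.5


def test_recovery_zero_particles():
    params = SimulationParams(
        n_loricae=150, seed=41,
        capture=CaptureModel(particles_per_lorica=0.0),
    )
    rep = recovery_experiment(params)
    assert rep.expected_mean_total == 0.0
    assert rep.observed_mean_total == 0.0
    assert rep.z_total == 0.0


def test_negative_binomial_counts_overdisperse():
    base = dict(n_loricae=300, seed=43)
    pois = simulate_dataset(SimulationParams(
        **base, capture=CaptureModel(count_distribution="poisson")))
    nb = simulate_dataset(SimulationParams(
        **base, capture=CaptureModel(count_distribution="negative_binomial",
                                     nb_dispersion=2.0)))
    def _var(ds):
        totals = [e.total for e in estimate_dataset(ds).values()]
        return np.var(totals)
    assert _var(nb) > _var(pois)
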