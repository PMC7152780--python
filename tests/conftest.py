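"""Shared simulation fixtures.

The expensive Monte-Carlo ensembles are simulated once per session and
reduced to correlation curves, fits and summary statistics that several
test modules share.  All seeds are fixed; problem sizes are the scaled-down
study conditions (50 molecules, 2-s acquisitions) with repetitions and,
where corral geometry matters, several pooled observation-spot positions.
"""

import numpy as np
import pytest

import corralfcs as cf
from corralfcs.correlate import (
    autocorrelate_direct,
    autocorrelate_multitau,
    average_curves,
)
from corralfcs.fcsfit import fit_fcs_2d, transit_to_D_spot

FREE_MASTER_SEED = 11
TRAP_MASTER_SEED = 95
HOP_MASTER_SEED = 83
PHOP_MASTER_SEED = 95

# pooled observation-spot positions (nm): averages over corral geometry the
# way measurements pool different membrane regions
CENTERS = [(0.0, 0.0), (600.0, 0.0), (-600.0, 0.0), (0.0, 600.0), (0.0, -600.0)]


def _avg_fit(curves):
    avg = average_curves(curves)
    return fit_fcs_2d(avg, (0.5, float(avg.lags[-1])))


def _mesh_curves(
    p_hop, seed_spacing, spots, n_rep, master, dt, p_trap=0.0, duration=2.0,
    centers=CENTERS,
):
    """Simulate n_rep ensembles (fresh mesh each) and correlate the readout
    of every spot FWHM at every pooled centre position."""
    cfg = cf.test_preset(
        p_trap=p_trap, p_hop=p_hop, dt=dt, duration=duration,
        seed_spacing=seed_spacing,
    )
    rng = np.random.default_rng(master)
    curves = {f: [] for f in spots}
    for _ in range(n_rep):
        mesh_seed = int(rng.integers(0, 2**31 - 1))
        sim_seed = int(rng.integers(0, 2**31 - 1))
        mesh = (
            cf.generate_corral_mesh(seed_spacing, cfg.arena_diameter, mesh_seed)
            if p_hop < 1.0
            else None
        )
        ens = cf.simulate_trajectories(cfg.replace(rng_seed=sim_seed), mesh)
        for f in spots:
            for ctr in centers:
                tr = cf.generate_intensity_trace(
                    ens, cf.GaussianSpot(center=ctr, fwhm=f)
                )
                curves[f].append(autocorrelate_multitau(tr))
    return curves


@pytest.fixture(scope="session")
def free_suite():
    """Ten free-diffusion repetitions (p_trap 0, p_hop 1; 50 molecules, 2 s,
    dt 0.002 ms) read through 250/100/50-nm spots, plus a line carpet, MSD
    and per-trace statistics."""
    spots = (250.0, 100.0, 50.0)
    cfg = cf.test_preset(p_trap=0.0, p_hop=1.0)
    rng = np.random.default_rng(FREE_MASTER_SEED)
    curves = {f: [] for f in spots}
    direct_250 = []
    pixel_xs = np.linspace(-175.0, 175.0, 8)
    pixel_curves = [[] for _ in pixel_xs]
    msd = None
    example_trace = None
    for rep in range(10):
        seed = int(rng.integers(0, 2**31 - 1))
        ens = cf.simulate_trajectories(
            cfg.replace(rng_seed=seed), record_unwrapped=(rep == 0)
        )
        for f in spots:
            tr = cf.generate_intensity_trace(ens, cf.GaussianSpot(fwhm=f))
            if f == 250.0:
                direct_250.append(autocorrelate_direct(tr, max_lag=200.0))
                if rep == 0:
                    example_trace = tr
            curves[f].append(autocorrelate_multitau(tr))
        for i, x in enumerate(pixel_xs):
            px = cf.generate_intensity_trace(
                ens,
                cf.GaussianSpot(center=(float(x), 0.0), fwhm=150.0),
                sampling_interval=0.47273,
            )
            pixel_curves[i].append(autocorrelate_multitau(px))
        if rep == 0:
            msd = cf.ensemble_msd(ens, 10.0)
    fits = {f: _avg_fit(cs) for f, cs in curves.items()}
    return {
        "config": cfg,
        "curves": curves,
        "fits": fits,
        "D": {f: transit_to_D_spot(fit.tau_D, f) for f, fit in fits.items()},
        "direct_avg_250": average_curves(direct_250),
        "pixel_curves": [average_curves(cs) for cs in pixel_curves],
        "msd": msd,
        "example_trace": example_trace,
    }


@pytest.fixture(scope="session")
def trap_suite():
    """Trapping-only ensembles (p_trap 5e-5 per 0.001-ms step, p_hop 1)
    read through 250/100/50-nm spots at pooled positions.  Acquisitions are
    6 s so that the slow trapped-molecule component is resolved by the fit
    rather than absorbed into the offset."""
    spots = (250.0, 100.0, 50.0)
    curves = _mesh_curves(
        p_hop=1.0, seed_spacing=50.0, spots=spots, n_rep=2,
        master=TRAP_MASTER_SEED, dt=0.001, p_trap=5e-5, duration=6.0,
        centers=CENTERS[:3],
    )
    fits = {f: _avg_fit(cs) for f, cs in curves.items()}
    return {"fits": fits, "D": {f: transit_to_D_spot(fit.tau_D, f) for f, fit in fits.items()}}


@pytest.fixture(scope="session")
def hop_suite():
    """Hop-dominated ensembles: a fine corral mesh (15-nm seed spacing,
    mesh size ~33 nm, well below every observation spot) with hindered
    boundary crossing (p_hop 0.05) and no trapping, read through 250- and
    50-nm spots at pooled positions.  In this regime the transit across a
    spot averages many corral crossings and the apparent D rises at small
    spots (the meshwork diffusion-law signature)."""
    spots = (250.0, 50.0)
    curves = _mesh_curves(
        p_hop=0.05, seed_spacing=15.0, spots=spots, n_rep=3,
        master=HOP_MASTER_SEED, dt=0.001,
    )
    fits = {f: _avg_fit(cs) for f, cs in curves.items()}
    return {"fits": fits, "D": {f: transit_to_D_spot(fit.tau_D, f) for f, fit in fits.items()}}


@pytest.fixture(scope="session")
def phop_matrix():
    """Apparent D per (p_hop, spot FWHM) on the 50-nm-spacing (110-nm mesh)
    corrals of the full-scale simulation conditions, pooled over
    repetitions and spot positions.

    Spot sizes are restricted to those above the mesh size (250/150/100 nm):
    below it the single-component fit no longer reads out macroscopic
    mobility (see docs/methods.md on the confinement-plateau artefact), and
    6-s acquisitions are used so the slow corral-escape component is
    resolved rather than absorbed into the offset."""
    spots = (250.0, 150.0, 100.0)
    matrix = {}
    for p_hop in (0.05, 0.2, 1.0):
        curves = _mesh_curves(
            p_hop=p_hop, seed_spacing=50.0, spots=spots, n_rep=2,
            master=PHOP_MASTER_SEED, dt=0.001, duration=6.0,
            centers=CENTERS[:3],
        )
        matrix[p_hop] = {
            f: transit_to_D_spot(_avg_fit(cs).tau_D, f) for f, cs in curves.items()
        }
    return matrix
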