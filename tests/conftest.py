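import numpy as np
import pytest

from condensquant import synthgen


@pytest.fixture
def two_level_field():
    """Noiseless one-channel field: 5 disks of radius 5, interior 10 / exterior 2."""
    centers = [[20, 20], [20, 60], [60, 20], [60, 60], [40, 40]]
    truth = synthgen.DropletTruth(
        centers=centers,
        radii=[5.0] * 5,
        channel_names=("mEGFP",),
        interior_levels=(10.0,),
        exterior_levels=(2.0,),
        seed=0,
    )
    field, _ = synthgen.gen_droplet_field(truth, (80, 80))
    return field, truth


@pytest.fixture
def single_cluster_profile():
    """Noiseless profile with one 400-nm-FWHM Gaussian cluster at px 100."""
    truth = synthgen.ProfileTruth(
        length_px=200,
        pixel_size_nm=100.0,
        cluster_centers_px=[100.0],
        cluster_fwhms_nm=[400.0],
        cluster_amplitudes=[3.0],
        baseline=1.0,
        noise_sd=0.0,
        seed=0,
    )
    return synthgen.gen_junction_profile(truth)


def make_noiseless_frap(y0=0.0, f_mob=0.6, tau_half=17.0, duration=300.0, interval=10.0):
    truth = synthgen.FrapTruth(
        y0=y0, f_mob=f_mob, tau_half_s=tau_half,
        interval_s=interval, duration_s=duration, noise_sd=0.0, seed=0,
    )
    frame, _ = synthgen.gen_frap_trace(truth)
    return frame, truth
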