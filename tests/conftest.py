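import numpy as np
import pytest

import chapkit as ck


@pytest.fixture(scope="session")
def small_truth():
    """50 kb circular genome, 20 genes, 12 well-separated planted peaks."""
    genome, genes = ck.generate_genome(50_000, 0.5, 20, seed=11)
    return ck.plant_peaks(genome, genes, 12, height_range=(100.0, 300.0),
                          width_range=(40.0, 120.0),
                          conditions=["iron", "heme"], seed=11)


@pytest.fixture()
def flat_track():
    return ck.CoverageTrack(chrom="chr", values=np.full(2000, 10.0))


def gaussian_bump_track(length, summits, heights, widths, background=0.0,
                        circular=True):
    """Noise-free track of Gaussian bumps parameterized by FWHM."""
    x = np.arange(length)
    v = np.full(length, float(background))
    for s, h, w in zip(summits, heights, widths):
        d = np.abs(x - s)
        if circular:
            d = np.minimum(d, length - d)
        sigma = w / (2.0 * np.sqrt(2.0 * np.log(2.0)))
        v += h * np.exp(-(d ** 2) / (2 * sigma ** 2))
    return ck.CoverageTrack(chrom="chr", values=v, circular=circular)


def match_summits(called, planted, length, tol):
    """(recall, precision, per-called-summit distance to nearest truth)."""
    if not planted:
        return float("nan"), float("nan"), []
    dists = [min(ck.circular_distance(c, s, length) for s in planted)
             for c in called]
    recovered = sum(
        1 for s in planted
        if any(ck.circular_distance(c, s, length) <= tol for c in called))
    recall = recovered / len(planted)
    precision = (sum(1 for d in dists if d <= tol) / len(called)
                 if called else float("nan"))
    return recall, precision, dists
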