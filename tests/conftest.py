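import numpy as np
import pytest

from editquant import melt
from editquant.ngs import LocusConfig
from editquant.synthetic import MeltModelParams, default_temperature_grid, simulate_mixture


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


@pytest.fixture(scope="session")
def locus() -> LocusConfig:
    """Synthetic amplicon locus: 107-nt target flanked by 21/20-nt primers.

    Dimensions mirror a typical intron-targeted editing amplicon (~150 bp
    product); all sequences are randomly generated with a fixed seed.
    """
    rng = np.random.default_rng(20170117)
    return LocusConfig(
        name="synthetic_locus",
        wild_type=_random_dna(rng, 107),
        sense_primer=_random_dna(rng, 21),
        antisense_primer=_random_dna(rng, 20),
        stringency=3,
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)


def hrma_roundtrip_estimates(noise_sd: float, n_replicates: int = 4, seed0: int = 1000):
    """Full HRMA calibration round trip on simulated mixes with known truth.

    Mirrors the bench protocol: each nominal mix fraction is melted in
    ``n_replicates`` wells, the difference curves are taken against the mean
    of the control (0 % mutant) replicates, and the replicate-mean DCA feeds
    the standard-curve fit and inversion.  Returns (nominal %, estimated %)
    pairs for fractions 0, 0.1, ..., 1.0.
    """
    grid = default_temperature_grid()
    window = melt.AnalysisWindow(70.0, 95.0)
    wt = MeltModelParams(tm=78.5, f_high=1000.0, f_low=50.0)
    mut = MeltModelParams(tm=77.0, f_high=1000.0, f_low=50.0)

    def replicates(fraction, base_seed):
        return [
            melt.normalize_melt_curve(
                simulate_mixture(fraction, wt, mut, grid, noise_sd=noise_sd,
                                 seed=base_seed + r), window)
            for r in range(n_replicates)
        ]

    controls = replicates(0.0, seed0)
    pts = []
    for i, f in enumerate(np.linspace(0.0, 1.0, 11)):
        mean_dca, _, _ = melt.replicate_dca(replicates(f, seed0 + 100 * (i + 1)), controls)
        pts.append((100.0 * f, mean_dca))
    std = melt.fit_standard_curve(pts)
    return [(nominal, melt.estimate_mutant_fraction(std, dca).percent)
            for nominal, dca in pts]
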