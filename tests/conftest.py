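import pytest

import porlab as pl
from porlab.simulate_ensemble import EnsembleDesign, make_reference, sample_ensemble


@pytest.fixture(scope="session")
def reference_trace() -> pl.StructureModel:
    """A 400-residue protein-like Cα reference trace."""
    return make_reference(400, seed=11)


@pytest.fixture(scope="session")
def two_family_ensemble(reference_trace):
    """Planted two-family ensemble: interface II displaced 8 Å in family 1,
    0.2 Å/axis jitter in all mobile regions, random global placement."""
    design = EnsembleDesign(
        n_members=40,
        jitter_sigma=0.2,
        family_offsets=[{}, {"interface_II": 8.0}],
        family_fractions=[0.5, 0.5],
        seed=23,
    )
    return sample_ensemble(design, reference_trace)


@pytest.fixture(scope="session")
def opt_titration_samples():
    """Dark + illuminated OPT-lipid NADPH titration with known constants."""
    params = pl.GeneratorParams(km_d=50.0, km_l=5.0, noise_sigma=0.01, seed=7)
    comp = pl.Composition(
        "Pchlide", "NADPH", 0.0, lipid="OPT", lipid_uM=400.0, isoform="HaPOR3"
    )
    from porlab.simulate_spectra import DEFAULT_NADPH_LADDER_UM

    return pl.simulate_titration(params, DEFAULT_NADPH_LADDER_UM, comp)
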