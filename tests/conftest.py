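import numpy as np
import pytest

from ioncal import (
    DIAAnalyte,
    FragmentPanel,
    SpectrumRecord,
    SyntheticDIAConfig,
    SyntheticInfusionConfig,
    TransitionTarget,
    simulate_dia_run,
    simulate_infusion,
)

GLUFIB_MZS = (480.23, 627.32, 684.35, 813.39, 942.43, 1056.47, 1171.50, 1285.54)


def make_spectrum(
    scan_index=0,
    rt=0.0,
    mz=(100.0, 200.0, 300.0),
    intensity=(1.0, 1.0, 1.0),
    injection_time=5.0,
    iso_center=np.nan,
    iso_width=np.nan,
    ms_level=2,
):
    return SpectrumRecord(
        scan_index=scan_index,
        retention_time=rt,
        ms_level=ms_level,
        isolation_center=iso_center,
        isolation_width=iso_width,
        injection_time=injection_time,
        mz_values=np.asarray(mz, dtype=float),
        intensities=np.asarray(intensity, dtype=float),
    )


@pytest.fixture
def glufib_panel():
    """The eight-fragment calibration panel with the 942.43 reference."""
    return FragmentPanel(target_mzs=GLUFIB_MZS, reference_mz=942.43, tolerance=10.0)


@pytest.fixture
def infusion_run(glufib_panel):
    """A seeded pure-Poisson infusion run (alpha_true = 1, no extra noise)."""
    config = SyntheticInfusionConfig(
        n_spectra=3000,
        fragment_mzs=GLUFIB_MZS,
        mean_ions_per_fill=tuple(np.linspace(500.0, 20000.0, 8)),
        injection_time=5.0,
        alpha_true=1.0,
        seed=11,
    )
    spectra, ledger = simulate_infusion(config)
    return config, spectra, ledger


@pytest.fixture
def dia_run():
    """A deterministic (noise-free) one-analyte DIA peak."""
    analyte = DIAAnalyte(
        analyte_id="PEP1",
        precursor_mz=502.5,
        fragment_mzs=(300.1, 401.2, 502.3),
        total_ions=4000.0,
        apex_rt=10.0,
        peak_fwhm=6.0,
    )
    config = SyntheticDIAConfig(analytes=(analyte,), noise_free=True, seed=5)
    spectra, ledger = simulate_dia_run(config)
    target = TransitionTarget(
        analyte_id="PEP1",
        precursor_mz=502.5,
        fragment_mzs=(300.1, 401.2, 502.3),
        boundary_start=9.0,
        boundary_end=11.0,
    )
    return config, spectra, ledger, target
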