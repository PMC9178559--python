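import numpy as np
import pytest

from xlstub.chem import DSSO, CrosslinkedPair, Peptide
from xlstub.io import Spectrum


@pytest.fixture
def dsso_pair():
    """Small DSSO-linked pair: AKAR linked at K2, KRFESA linked at K1."""
    alpha = Peptide("AKAR", frozenset({"PA"}), start_position=10)
    beta = Peptide("KRFESA", frozenset({"PB"}), start_position=5)
    return CrosslinkedPair(alpha, beta, 2, 1, DSSO, precursor_charge=3)


def random_spectrum(rng: np.random.Generator, ms_level: int = 2, n_peaks: int = 30) -> Spectrum:
    mzs = np.sort(rng.uniform(100, 1500, size=n_peaks))
    intens = rng.lognormal(1.0, 1.0, size=n_peaks)
    kwargs = {}
    if ms_level == 3:
        kwargs = {"parent_scan_id": f"p{rng.integers(1e6)}", "selected_precursor_mz": float(rng.uniform(200, 900))}
    return Spectrum(
        scan_id=f"s{rng.integers(1e9)}",
        ms_level=ms_level,
        precursor_mz=float(rng.uniform(300, 1200)),
        precursor_charge=int(rng.integers(2, 6)),
        peaks=list(zip(mzs.tolist(), intens.tolist())),
        retention_time=float(rng.uniform(0, 7200)),
        **kwargs,
    )
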