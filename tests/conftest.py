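import numpy as np
import pytest

from quinox import (
    CVSpec,
    SurfaceRedoxParams,
    detect_peaks,
    simulate_cv,
)

# Published quinone composition of the two nitrifier isolates: methyl-PQ
# (n, m) -> (printed measured [M+H]+ m/z, printed [M+H]+ formula,
#            abundance % N. inopinata, abundance % N. moscoviensis)
# None = not detected; 0.05 encodes a "< 0.1" entry.
TABLE_ROWS = {
    (6, 6): (559.451, "C39H59O2", 1.6, None),
    (6, 5): (561.467, "C39H61O2", 0.3, None),
    (7, 7): (627.515, "C44H67O2", 40.0, 0.1),
    (7, 6): (629.530, "C44H69O2", 1.4, None),
    (8, 8): (695.577, "C49H75O2", 45.3, 2.1),
    (8, 7): (697.592, "C49H77O2", 10.8, None),
    (9, 9): (763.639, "C54H83O2", 0.6, 67.1),
    (9, 8): (765.654, "C54H85O2", 0.1, None),
    (10, 10): (831.701, "C59H91O2", 0.05, 29.2),
    (11, 11): (899.764, "C64H99O2", None, 1.5),
}


@pytest.fixture(scope="session")
def reversible_params():
    """Langmuir/reversible limit: no interactions, fast kinetics, 298 K."""
    return SurfaceRedoxParams(
        e0=-0.142, n_e=2, gamma_T=1e-10, k_s=500.0, alpha=0.5,
        a_ox=0.0, a_red=0.0, temperature=298.0, area_cm2=0.126,
    )


@pytest.fixture(scope="session")
def reversible_cv(reversible_params):
    """Fine-grid (0.2 mV) simulation of the reversible limit."""
    return simulate_cv(
        reversible_params, 0.1, -0.45, scan_rate=0.02, points_per_segment=2751
    )


@pytest.fixture(scope="session")
def reversible_peaks(reversible_cv):
    return detect_peaks(reversible_cv)
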