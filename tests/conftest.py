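import pytest

from kymoflow.correction import Direction, ScanParameters


@pytest.fixture
def antero_scan() -> ScanParameters:
    """10 mm/s anterograde scan, 1 ms line period (units: um, mm/s, ms)."""
    return ScanParameters(
        v_scan=10.0, direction=Direction.ANTEROGRADE, t_line=1.0, x_pixel=0.2, n_pixels=30
    )


@pytest.fixture
def retro_scan(antero_scan: ScanParameters) -> ScanParameters:
    return antero_scan.with_direction(Direction.RETROGRADE)
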