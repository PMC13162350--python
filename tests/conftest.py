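import numpy as np
import pytest

from scspace.climate import AnnualClimate, ClimateCube
from scspace.config import PipelineConfig, SimulateBlock
from scspace.envelope import CropLayer
from scspace.grids import GridSpec
from scspace.synthetic import CropTruthParams


@pytest.fixture
def small_spec() -> GridSpec:
    return GridSpec(10, 10, -10.0, 10.0, 0.0, 20.0)


@pytest.fixture
def tropical_spec() -> GridSpec:
    return GridSpec(50, 50, -30.0, 30.0, -30.0, 30.0)


def make_cube(spec: GridSpec, tavg, prec, source="baseline") -> ClimateCube:
    """Broadcast scalars/fields to (12, rows, cols) monthly layers."""
    t = np.broadcast_to(np.asarray(tavg, dtype=float), (12, *spec.shape)).copy()
    p = np.broadcast_to(np.asarray(prec, dtype=float), (12, *spec.shape)).copy()
    return ClimateCube(spec=spec, tavg=t, prec=p, source=source)


def make_annual(spec: GridSpec, t_ann, p_ann) -> AnnualClimate:
    t = np.broadcast_to(np.asarray(t_ann, dtype=float), spec.shape).copy()
    p = np.broadcast_to(np.asarray(p_ann, dtype=float), spec.shape).copy()
    return AnnualClimate(spec=spec, t_ann=t, p_ann=p)


def line_grid(n: int) -> GridSpec:
    """1 x n grid: a weighted point set laid out as a raster."""
    return GridSpec(1, n, -0.5, 0.5, 0.0, float(n))


def point_set_layers(t, p, w, crop_name="crop"):
    """Wrap 1-D climate/production samples as rasters on a 1 x n grid."""
    t = np.asarray(t, dtype=float)
    n = t.size
    spec = line_grid(n)
    annual = AnnualClimate(
        spec=spec,
        t_ann=t.reshape(1, n),
        p_ann=np.asarray(p, dtype=float).reshape(1, n),
    )
    crop = CropLayer(
        crop_name=crop_name,
        production=np.asarray(w, dtype=float).reshape(1, n),
        spec=spec,
    )
    return annual, crop


def recovery_config(seed: int, fractions: dict[str, float]) -> PipelineConfig:
    """Single-crop planted-truth pipeline config used by recovery tests."""
    crop = CropTruthParams(
        "maize", (20.0, 26.0), (800.0, 1800.0),
        frac_outside_baseline=0.0, anchor_mass=0.06,
    )
    sim = SimulateBlock(
        crops=(crop,), future_mode="planted", planted_fractions=dict(fractions),
    )
    return PipelineConfig(seed=seed, simulate=sim)
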