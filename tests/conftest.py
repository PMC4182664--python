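"""Shared fixtures and randomized-parameter helpers."""

import dataclasses
import math

import numpy as np
import pytest
from hypothesis import strategies as st

from saberbite.skull import SkullParams, generate, preset


@pytest.fixture
def bulldogging_params():
    return preset("bulldogging")


@pytest.fixture
def bulldogging(bulldogging_params):
    return generate(bulldogging_params)


def random_params(rng: np.random.Generator, noise_mm: float = 0.0) -> SkullParams:
    """Draw a valid random parameter set (uniform over sensible anatomy).

    Extension is kept within the range where the virtual point stays
    anteroventral to the TMJ for the drawn offsets, and the canine
    radius is capped so the canine base lands on the upper toothrow.
    """
    tmj_upper = rng.uniform(120.0, 250.0)
    vp_ant = rng.uniform(5.0, 30.0)
    vp_vent = rng.uniform(8.0, 35.0)
    r_max = min(150.0, tmj_upper - vp_ant - 10.0)
    radius = rng.uniform(vp_vent + 10.0, r_max)
    ext_lo, ext_hi = _extension_window(vp_ant, vp_vent)
    return SkullParams(
        caudal_to_mid_mm=rng.uniform(60.0, 200.0),
        mid_to_aoj_mm=rng.uniform(60.0, 200.0),
        aoj_to_tmj_mm=rng.uniform(40.0, 150.0),
        tmj_to_upper_incisor_mm=tmj_upper,
        tmj_to_lower_incisor_mm=rng.uniform(100.0, 220.0),
        canine_radius_mm=radius,
        virtual_point_anterior_mm=vp_ant,
        virtual_point_ventral_mm=vp_vent,
        gape_deg=rng.uniform(10.0, 170.0),
        extension_deg=rng.uniform(ext_lo, ext_hi),
        canine_span_deg=rng.uniform(15.0, 60.0),
        noise_mm=noise_mm,
        seed=int(rng.integers(0, 2**31 - 1)),
    )


def _extension_window(vp_ant: float, vp_vent: float,
                      jaw_offset: float = -36.0,
                      margin: float = 2.0) -> tuple[float, float]:
    """Extension range keeping the virtual point anteroventral to the TMJ.

    The virtual point is cranium-fixed, so pitching the cranium rotates
    its offset from the TMJ; the admissible window is 90 degrees wide
    and depends on the offset's own polar angle.
    """
    alpha = math.degrees(math.atan2(-vp_vent, vp_ant))  # in (-90, 0)
    lo = -jaw_offset - 90.0 - alpha + margin
    hi = -jaw_offset - alpha - margin
    return max(lo, 5.0), min(hi, 80.0)


@st.composite
def skull_params_strategy(draw) -> SkullParams:
    """Hypothesis analogue of :func:`random_params`."""
    f = lambda lo, hi: st.floats(lo, hi, allow_nan=False, allow_infinity=False)
    tmj_upper = draw(f(120.0, 250.0))
    vp_ant = draw(f(5.0, 30.0))
    vp_vent = draw(f(8.0, 35.0))
    radius = draw(f(vp_vent + 10.0, min(150.0, tmj_upper - vp_ant - 10.0)))
    ext_lo, ext_hi = _extension_window(vp_ant, vp_vent)
    return SkullParams(
        caudal_to_mid_mm=draw(f(60.0, 200.0)),
        mid_to_aoj_mm=draw(f(60.0, 200.0)),
        aoj_to_tmj_mm=draw(f(40.0, 150.0)),
        tmj_to_upper_incisor_mm=tmj_upper,
        tmj_to_lower_incisor_mm=draw(f(100.0, 220.0)),
        canine_radius_mm=radius,
        virtual_point_anterior_mm=vp_ant,
        virtual_point_ventral_mm=vp_vent,
        gape_deg=draw(f(10.0, 170.0)),
        extension_deg=draw(f(ext_lo, ext_hi)),
        canine_span_deg=draw(f(15.0, 60.0)),
    )


def perturbed(params: SkullParams, **overrides) -> SkullParams:
    return dataclasses.replace(params, **overrides)


def assert_points_close(p, q, tol, scale=1.0):
    d = math.hypot(p.x - q.x, p.y - q.y)
    assert d <= tol * scale, f"points differ by {d} (> {tol * scale})"
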