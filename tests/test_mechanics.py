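"""Pressure proxy, resistance, volumetric flow rate, phase labels, mechanism."""

import numpy as np
import pytest

from tubepump.errors import InvalidConfigurationError, UndefinedAngleError
from tubepump.lumen_measure import LumenTrace
from tubepump.mechanics import (
    classify_mechanism,
    flow_resistance,
    label_phases,
    pressure_gradient,
    smooth_derivative,
    volumetric_flow_rate,
    wall_pressure_term,
)
from tubepump.scenarios import truth_hemodynamics


def _trace(areas, dt=0.01, closed=None, pixel_area=4.0, label="L1"):
    areas = np.asarray(areas, dtype=float)
    n = len(areas)
    closed = np.zeros(n, bool) if closed is None else np.asarray(closed, bool)
    return LumenTrace(label, np.arange(n) * dt, areas, np.zeros(n),
                      areas[:, None], closed, pixel_area)


def test_smooth_derivative_of_sinusoid():
    t = np.arange(100) / 100.0  # one full 1 Hz period
    y = np.sin(2 * np.pi * t)
    d = smooth_derivative(y, 0.01)
    truth = 2 * np.pi * np.cos(2 * np.pi * t)
    assert np.max(np.abs(d - truth)) < 0.01 * np.max(np.abs(truth))


def test_smooth_derivative_constants_and_errors():
    assert np.allclose(smooth_derivative(np.full(50, 3.0), 0.01), 0.0)
    with pytest.raises(InvalidConfigurationError):
        smooth_derivative(np.arange(4, dtype=float), 0.01)
    with pytest.raises(InvalidConfigurationError):
        smooth_derivative(np.arange(10, dtype=float), 0.01, window=11)


def test_wall_pressure_term_exponential_area():
    """A = A0 exp(kt) gives p_w = -k exactly (polynomial-exact interior)."""
    k = 2.0
    t = np.arange(60) * 0.01
    tr = _trace(1000.0 * np.exp(k * t))
    p = wall_pressure_term(tr)
    interior = slice(5, 55)  # circular padding corrupts the wrap ends
    assert np.allclose(p[interior], -k, rtol=0.01)


def test_wall_pressure_sign_and_mask():
    t = np.arange(50) * 0.01
    grow = _trace(1000 + 100 * t / t.max())
    assert np.all(wall_pressure_term(grow)[5:45] < 0)  # expansion = suction
    closed = np.zeros(50, bool)
    closed[:10] = True
    tr = _trace(np.linspace(10, 500, 50), closed=closed)
    p = wall_pressure_term(tr)
    assert np.isnan(p[:10]).all()


def test_pressure_gradient_symmetry_and_closed_form():
    k = 1.5
    t = np.arange(60) * 0.01
    same = _trace(2000 + 500 * np.sin(2 * np.pi * t / 0.6))
    assert np.allclose(pressure_gradient(same, same), 0.0, atol=1e-12)
    l1 = _trace(1000.0 * np.exp(k * t))
    l3 = _trace(np.full(60, 1500.0), label="L3")
    g = pressure_gradient(l1, l3)
    # L1 expanding: local suction upstream, so the L1->L3 gradient is -k
    assert np.allclose(g[5:55], -k, rtol=0.01)


def test_flow_resistance_range_and_closure():
    aa = np.array([3000, 2000, 500, 50, 10, 10, 400, 2500, 3000], dtype=float)
    closed = aa < 16
    rn = flow_resistance(aa, closed_flag=closed, area_floor_um2=16.0)
    assert rn.min() == 0.0 and rn.max() == 1.0
    assert np.all(rn[closed] == 1.0)
    assert rn[0] == 0.0  # largest area -> lowest resistance


def test_flow_resistance_proportionality():
    # halving the area doubles the raw resistance: check via normalized spacing
    aa = np.array([4000.0, 2000.0, 1000.0])
    rn = flow_resistance(aa, area_floor_um2=16.0)
    raw = 1.0 / aa
    expect = (raw - raw.min()) / (raw.max() - raw.min())
    assert np.allclose(rn, expect)


def test_flow_resistance_degenerate_warns():
    with pytest.warns(UserWarning):
        rn = flow_resistance(np.full(10, 1234.0))
    assert np.allclose(rn, 0.0)


def test_volumetric_flow_rate_closed_forms():
    n = 121
    yy, xx = np.mgrid[0:n, 0:n]
    c = (n - 1) / 2.0
    dist = np.hypot(yy - c, xx - c)
    mask = dist < 50
    # uniform velocity: V = v0 * A
    v0 = 2.0
    v_img = np.full((n, n), v0)
    V = volumetric_flow_rate(v_img, mask, 0.0, 1.0)
    assert V == pytest.approx(v0 * 1e3 * mask.sum(), rel=1e-9)
    # Poiseuille with centreline vc: V = vc * pi R^2 / 2
    vc = 4.0
    v_img = vc * np.clip(1 - (dist / 50) ** 2, 0, None)
    V = volumetric_flow_rate(v_img, mask, 0.0, 1.0)
    assert V == pytest.approx(vc * 1e3 * np.pi * 50**2 / 2, rel=0.02)
    # theta = 60 deg doubles the divide-corrected rate
    V60 = volumetric_flow_rate(v_img, mask, np.deg2rad(60.0), 1.0)
    assert V60 == pytest.approx(2 * V, rel=1e-9)
    # multiply variant halves instead
    Vm = volumetric_flow_rate(v_img, mask, np.deg2rad(60.0), 1.0,
                              angle_correction="multiply")
    assert Vm == pytest.approx(0.5 * V, rel=1e-9)


def test_volumetric_flow_rate_errors_and_empty():
    img = np.ones((8, 8))
    with pytest.raises(UndefinedAngleError):
        volumetric_flow_rate(img, np.ones((8, 8), bool), np.pi / 2, 1.0)
    assert volumetric_flow_rate(img, np.zeros((8, 8), bool), 0.0, 1.0) == 0.0


def test_label_phases_sinusoid_one_cycle():
    t = np.arange(50) * 0.01
    a = 2000 + 800 * np.sin(2 * np.pi * t / 0.5)
    l1, l3 = _trace(a), _trace(a, label="L3")
    labels = label_phases(l1, l3)
    kinds = [lab for _, _, lab in labels.intervals]
    assert kinds.count("relaxation") == 1 and kinds.count("contraction") == 1
    # tiling covers the full cycle
    total = sum((e - s) % 50 for s, e, _ in labels.intervals)
    assert total == 50


def test_ventricle_relaxation_longer_than_contraction(vent_scenario):
    _, tr1, tr3 = truth_hemodynamics(vent_scenario, seed=0)
    labels = label_phases(tr1, tr3)
    dur = {lab: 0 for lab in ("relaxation", "contraction", "closed")}
    n = len(labels.labels)
    for s, e, lab in labels.intervals:
        dur[lab] = dur.get(lab, 0) + (e - s) % n
    assert dur["relaxation"] > dur["contraction"]


def test_outflow_opens_faster_than_it_closes(outflow_scenario):
    _, tr1, tr3 = truth_hemodynamics(outflow_scenario, seed=0)
    d1 = smooth_derivative(tr1.areas_mean_um2, 0.01)
    assert d1.max() > 1.5 * np.abs(d1.min())  # fast opening, slow closing


def test_classify_mechanism_on_coupled_series(vent_scenario):
    series, tr1, tr3 = truth_hemodynamics(vent_scenario, seed=0)
    labels = label_phases(tr1, tr3)
    rep = classify_mechanism(series.pressure_gradient, series.flow_rate_um3_s,
                             labels, series.low_resistance_mask)
    assert rep["tag"] in ("mixed", "suction", "pushing")
    evid = [iv["evidence"] for iv in rep["intervals"] if iv["evidence"] is not None]
    assert len(evid) > 0


def test_classify_mechanism_independent_noise_rarely_directional():
    """Unrelated G and V must not produce consistent mechanism calls."""
    t = np.arange(50) * 0.01
    a = 2000 + 800 * np.sin(2 * np.pi * t / 0.5)
    l1, l3 = _trace(a), _trace(a, label="L3")
    labels = label_phases(l1, l3)
    rng = np.random.default_rng(7)
    tags = []
    for _ in range(60):
        g = rng.standard_normal(50)
        v = rng.standard_normal(50)
        rep = classify_mechanism(g, v, labels, np.ones(50, bool))
        tags.append(rep["tag"])
    directional = sum(t in ("suction", "pushing") for t in tags)
    assert directional < 30  # indeterminate/mixed dominates
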