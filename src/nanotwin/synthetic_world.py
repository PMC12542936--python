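"""Seeded generators for every input the rest of the package consumes.

Virtual dishes of adherent cells with nucleus masks and per-cell ROS/RNS
kinetics, paired current/fluorescence draws with a tunable population
correlation, amperometric traces with programmed contact/insertion/
withdrawal events, and rendered bright-field-like frames with complete
ground truth.  Every generator is a pure function of (config, seed).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import yaml

from .electrochem import CurrentTrace, SensorCalibration, calibration_current
from .vision import ImageStack

__all__ = [
    "VirtualCell",
    "VirtualDish",
    "PairGenConfig",
    "fixture_config",
    "make_dish",
    "make_paired_measurements",
    "render_frames",
    "make_trace",
]


def fixture_config() -> dict:
    """The central fixtures config (parsed fixtures.yaml)."""
    text = resources.files("nanotwin.data").joinpath("fixtures.yaml").read_text()
    return yaml.safe_load(text)


def _ellipse_polygon(center, axes, angle, n: int = 64) -> np.ndarray:
    """Closed CCW polygon approximating a rotated ellipse, (n, 2) xy."""
    t = np.linspace(0.0, 2.0 * math.pi, n, endpoint=False)
    ca, sa = math.cos(angle), math.sin(angle)
    x = axes[0] * np.cos(t)
    y = axes[1] * np.sin(t)
    return np.column_stack([center[0] + x * ca - y * sa,
                            center[1] + x * sa + y * ca])


@dataclass
class VirtualCell:
    """Ground-truth cell: geometry in um plus biopsy-relevant attributes."""

    center: tuple                       # (x, y) um
    axes: tuple                         # semi-axes um
    angle: float                        # rad
    nucleus_axes: tuple                 # semi-axes um
    adherent: bool = True
    escape_probability: float = 0.02
    death_probability_per_attempt: float = 0.04
    ros_c0: float = 1.0                 # mM, cytoplasmic; ~0 in the nucleus
    tau: float = 12.0                   # s
    mito_density: float = 1.0           # a.u., latent readout for fluorescence
    membrane_compliance: float = 2.0    # um of deformation before penetration

    def __post_init__(self) -> None:
        for p in (self.escape_probability, self.death_probability_per_attempt):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must be in [0, 1]")
        if not (self.nucleus_axes[0] < self.axes[0]
                and self.nucleus_axes[1] < self.axes[1]):
            raise ValueError("nucleus must fit inside the cell")

    @property
    def contour(self) -> np.ndarray:
        return _ellipse_polygon(self.center, self.axes, self.angle)

    @property
    def nucleus_contour(self) -> np.ndarray:
        return _ellipse_polygon(self.center, self.nucleus_axes, self.angle)

    def ros_at(self, point) -> float:
        """Local ROS/RNS concentration: c0 in cytoplasm, ~0 in the nucleus."""
        if self._inside(point, self.nucleus_axes):
            return 0.02 * self.ros_c0
        if self._inside(point, self.axes):
            return self.ros_c0
        return 0.0

    @property
    def cytoplasm_point(self) -> tuple:
        """A point midway across the cytoplasm band, along the major axis."""
        r = 0.5 * (self.nucleus_axes[0] + self.axes[0])
        return (self.center[0] + r * math.cos(self.angle),
                self.center[1] + r * math.sin(self.angle))

    def _inside(self, point, axes) -> bool:
        dx = point[0] - self.center[0]
        dy = point[1] - self.center[1]
        ca, sa = math.cos(-self.angle), math.sin(-self.angle)
        u = dx * ca - dy * sa
        v = dx * sa + dy * ca
        return (u / axes[0]) ** 2 + (v / axes[1]) ** 2 <= 1.0


@dataclass
class VirtualDish:
    cells: list
    field_of_view: tuple                # (width, height) um
    seed: int = 0

    def to_json(self) -> str:
        payload = {
            "field_of_view": list(self.field_of_view),
            "seed": self.seed,
            "cells": [
                {**asdict(c),
                 "center": list(c.center), "axes": list(c.axes),
                 "nucleus_axes": list(c.nucleus_axes)}
                for c in self.cells
            ],
        }
        return json.dumps(payload, indent=1, sort_keys=True)

    def save(self, path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def from_json(cls, text: str) -> "VirtualDish":
        payload = json.loads(text)
        cells = [VirtualCell(
            center=tuple(c["center"]), axes=tuple(c["axes"]), angle=c["angle"],
            nucleus_axes=tuple(c["nucleus_axes"]), adherent=c["adherent"],
            escape_probability=c["escape_probability"],
            death_probability_per_attempt=c["death_probability_per_attempt"],
            ros_c0=c["ros_c0"], tau=c["tau"], mito_density=c["mito_density"],
            membrane_compliance=c["membrane_compliance"],
        ) for c in payload["cells"]]
        return cls(cells=cells, field_of_view=tuple(payload["field_of_view"]),
                   seed=payload["seed"])

    @classmethod
    def load(cls, path) -> "VirtualDish":
        return cls.from_json(Path(path).read_text())


@dataclass
class PairGenConfig:
    n_points: int = 89
    coupling_rho: float = 0.65
    current_noise_sd: float = 0.0       # extra independent noise, pA
    fluor_noise_sd: float = 0.0         # extra independent noise, a.u.

    def __post_init__(self) -> None:
        if not -1.0 <= self.coupling_rho <= 1.0:
            raise ValueError("|coupling_rho| must be <= 1")


class PackingError(RuntimeError):
    pass


def make_dish(n_cells: int, fov: tuple = (620.0, 500.0), seed: int = 0,
              config: Optional[dict] = None) -> VirtualDish:
    """Rejection-sample a dish of non-overlapping elliptical cells.

    Per-cell depletion time constants are log-normal with the configured
    median, concentrations uniform over the configured range, adhesion
    Bernoulli; everything derives from the seed.
    """
    if n_cells < 0:
        raise ValueError("n_cells must be >= 0")
    cfg = (config or fixture_config())["dish"]
    rng = np.random.default_rng(seed)
    r_lo, r_hi = cfg["cell_radius_um"]
    placed = []   # (center, max_radius)
    cells = []
    tries = 0
    while len(cells) < n_cells:
        tries += 1
        if tries > cfg["max_place_tries"]:
            raise PackingError(f"could not place {n_cells} cells in {fov}")
        axes = (rng.uniform(r_lo, r_hi), rng.uniform(r_lo, r_hi))
        rmax = max(axes)
        cx = rng.uniform(rmax, fov[0] - rmax)
        cy = rng.uniform(rmax, fov[1] - rmax)
        if any(math.hypot(cx - px, cy - py) < 0.95 * (rmax + pr)
               for (px, py), pr in placed):
            continue
        angle = rng.uniform(0.0, math.pi)
        ns_lo, ns_hi = cfg["nucleus_scale"]
        nscale = rng.uniform(ns_lo, ns_hi)
        adherent = bool(rng.random() < cfg["adherent_prob"])
        tau = float(np.exp(np.log(cfg["tau_s_median"])
                           + cfg["tau_s_sigma"] * rng.standard_normal()))
        c_lo, c_hi = cfg["ros_c0_mM"]
        ros_c0 = float(rng.uniform(c_lo, c_hi))
        m_lo, m_hi = cfg["membrane_compliance_um"]
        cell = VirtualCell(
            center=(cx, cy), axes=axes, angle=angle,
            nucleus_axes=(nscale * axes[0], nscale * axes[1]),
            adherent=adherent,
            escape_probability=(cfg["escape_prob_adherent"] if adherent
                                else cfg["escape_prob_loose"]),
            death_probability_per_attempt=cfg["death_prob_per_attempt"],
            ros_c0=ros_c0, tau=tau,
            mito_density=ros_c0 * float(rng.uniform(0.8, 1.2)),
            membrane_compliance=float(rng.uniform(m_lo, m_hi)),
        )
        placed.append(((cx, cy), rmax))
        cells.append(cell)
        tries = 0
    return VirtualDish(cells=cells, field_of_view=tuple(fov), seed=seed)


def make_paired_measurements(cfg: PairGenConfig, seed: int = 0) -> np.ndarray:
    """(n, 2) array of (current pA, fluorescence a.u.) with population
    Pearson correlation equal to ``coupling_rho`` (before extra noise)."""
    rho = cfg.coupling_rho
    rng = np.random.default_rng(seed)
    p = fixture_config()["pairs"]
    z = rng.standard_normal(cfg.n_points)
    w = rng.standard_normal(cfg.n_points)
    latent_c = rho * z + math.sqrt(max(0.0, 1.0 - rho * rho)) * w
    current = p["current_mean_pA"] + p["current_sd_pA"] * latent_c
    fluor = p["fluor_mean"] + p["fluor_sd"] * z
    if cfg.current_noise_sd > 0:
        current = current + rng.normal(0, cfg.current_noise_sd, cfg.n_points)
    if cfg.fluor_noise_sd > 0:
        fluor = fluor + rng.normal(0, cfg.fluor_noise_sd, cfg.n_points)
    return np.column_stack([current, fluor])


# ---------------------------------------------------------------------------
# Frame rendering

def _paint_ellipse(img, center_px, axes_px, angle, value):
    h, w = img.shape
    yy, xx = np.mgrid[0:h, 0:w]
    dx = xx - center_px[0]
    dy = yy - center_px[1]
    ca, sa = math.cos(-angle), math.sin(-angle)
    u = dx * ca - dy * sa
    v = dx * sa + dy * ca
    inside = (u / axes_px[0]) ** 2 + (v / axes_px[1]) ** 2 <= 1.0
    img[inside] += value
    return inside


def _paint_needle(img, tip_px, angle_deg, length_px, width_px, value):
    h, w = img.shape
    yy, xx = np.mgrid[0:h, 0:w]
    th = math.radians(angle_deg)
    ux, uy = math.cos(th), math.sin(th)
    dx = xx - tip_px[0]
    dy = yy - tip_px[1]
    along = dx * ux + dy * uy          # >= 0 behind the tip
    perp = np.abs(-dx * uy + dy * ux)
    mask = (along >= 0) & (along <= length_px) & (perp <= width_px / 2.0)
    img[mask] += value


def render_frames(dish: VirtualDish, trajectory: Sequence, optics: Optional[dict] = None,
                  contact_intervals: Optional[Sequence] = None,
                  needle_angle_deg: float = 45.0, seed: int = 0,
                  frame_shape: Optional[tuple] = None) -> tuple:
    """Render a bright-field-like stack plus complete ground truth.

    ``trajectory`` is a per-frame list of tip (x, y) positions in um (or
    None for "no probe in frame"); ``contact_intervals`` is a list of
    (start_frame, end_frame) during which a membrane-deformation ripple is
    animated at the tip.  Returns ``(ImageStack, ground_truth_dict)``.
    """
    opt = dict(fixture_config()["optics"])
    if optics:
        opt.update(optics)
    px = opt["pixel_size_um"]
    if frame_shape is None:
        frame_shape = (int(round(dish.field_of_view[1] / px)),
                       int(round(dish.field_of_view[0] / px)))
    h, w = frame_shape
    rng = np.random.default_rng(seed)

    base = np.full((h, w), opt["background_level"])
    cell_label = np.zeros((h, w), dtype=np.int32)
    for k, cell in enumerate(dish.cells, start=1):
        c_px = (cell.center[0] / px, cell.center[1] / px)
        a_px = (cell.axes[0] / px, cell.axes[1] / px)
        inside = _paint_ellipse(base, c_px, a_px, cell.angle, opt["cell_contrast"])
        cell_label[inside] = k
        n_px = (cell.nucleus_axes[0] / px, cell.nucleus_axes[1] / px)
        _paint_ellipse(base, c_px, n_px, cell.angle, opt["nucleus_contrast"])

    contact_intervals = contact_intervals or []
    in_contact = np.zeros(len(trajectory), dtype=bool)
    for t0, t1 in contact_intervals:
        in_contact[t0:t1] = True

    frames = np.empty((len(trajectory), h, w))
    tip_truth = []
    for t, tip in enumerate(trajectory):
        img = base.copy()
        if tip is not None:
            tip_px = (tip[0] / px, tip[1] / px)
            _paint_needle(img, tip_px, needle_angle_deg,
                          length_px=max(h, w), width_px=opt["needle_width_px"],
                          value=opt["needle_contrast"])
            if in_contact[t]:
                # membrane indentation ripple: oscillating dimple at the tip
                yy, xx = np.mgrid[0:h, 0:w]
                r2 = (xx - tip_px[0]) ** 2 + (yy - tip_px[1]) ** 2
                amp = 0.12 * (1.0 + 0.8 * math.sin(2.0 * math.pi * t / 3.0))
                img -= amp * np.exp(-r2 / (2.0 * 4.0 ** 2))
            tip_truth.append((tip_px[0], tip_px[1]))
        else:
            tip_truth.append(None)
        img = img + rng.normal(0.0, opt["noise_sd"], size=img.shape)
        frames[t] = np.clip(img, 0.0, 1.0)

    stack = ImageStack(frames=frames, frame_rate=opt["frame_rate_Hz"], pixel_size=px)
    truth = {
        "tip_px": tip_truth,
        "cell_label": cell_label,
        "contact_frames": in_contact,
        "background": base,
        "pixel_size_um": px,
    }
    return stack, truth


def make_trace(cell: VirtualCell, t_contact: float = 0.5, hold: float = 2.0,
               cal: Optional[SensorCalibration] = None, noise_sd: float = 0.5,
               seed: int = 0, insertion_speed: float = 200.0,
               sample_rate: float = 1000.0, post: float = 0.5,
               baseline: float = 0.0, insertion_point: Optional[tuple] = None) -> CurrentTrace:
    """Generative twin of an insertion/sense/withdraw current recording.

    Timeline: approach at ``insertion_speed`` (um/s); contact at
    ``t_contact``; the membrane deforms by the cell's compliance before the
    current steps up at penetration; the current then decays exponentially
    with the cell's tau while inside; after ``hold`` seconds inside, the
    probe withdraws and the current returns to baseline.  The position
    channel (um, along the probe axis) is synthesized from the same
    kinematics.  Annotations: contact, insert, withdraw_start.
    """
    cal = cal or SensorCalibration()
    deform_t = cell.membrane_compliance / insertion_speed
    t_insert = t_contact + deform_t
    t_withdraw = t_insert + hold
    total = t_withdraw + post
    n = int(round(total * sample_rate))
    t = np.arange(n) / sample_rate

    point = insertion_point if insertion_point is not None else cell.cytoplasm_point
    c_local = cell.ros_at(point)
    step = calibration_current(cal, c_local) - cal.intercept

    current = np.full(n, baseline)
    inside = (t >= t_insert) & (t < t_withdraw)
    current[inside] += step * np.exp(-(t[inside] - t_insert) / cell.tau)

    # probe-axis position: approach, deform, hold, retract
    pos = np.empty(n)
    pre = t < t_contact
    pos[pre] = (t[pre] - t_contact) * insertion_speed          # negative: approaching
    deform = (t >= t_contact) & (t < t_insert)
    pos[deform] = (t[deform] - t_contact) * insertion_speed    # pushing into membrane
    hold_m = inside
    pos[hold_m] = cell.membrane_compliance
    wd = t >= t_withdraw
    pos[wd] = cell.membrane_compliance - (t[wd] - t_withdraw) * insertion_speed

    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        current = current + rng.normal(0.0, noise_sd, size=n)
    return CurrentTrace(
        current=current, sample_rate=sample_rate, position=pos,
        annotations=[(t_contact, "contact"), (t_insert, "insert"),
                     (t_withdraw, "withdraw_start")],
    )
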