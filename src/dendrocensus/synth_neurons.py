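"""Parametric pyramidal-cell skeletons with known ground-truth morphometrics.

Each synthetic neuron is built in the standardized frame (pia at depth 0,
depth increasing with y) from closed-form geometry so that the six
morphometric descriptors are exact by construction:

* a vertical apical trunk from the soma up to a termination depth, topped by
  two horizontal tuft arms whose tip-to-tip extent equals the requested
  apical width (total apical length = trunk + arms, exactly);
* two straight basal segments from the soma whose lengths and depth offsets
  solve for the requested total basal length and the signed depth offset of
  the length-weighted basal center of mass (the basal bias), with the deeper
  segment pinning the lowest skeleton node and hence the height;
* optional short horizontal oblique branches off the trunk (they belong to
  neither apical nor basal totals and do not change the depth extremes).

Polylines are subdivided at ~1 μm node spacing; subdivision changes no
descriptor.  A neuron can optionally be embedded into a synthetic tilted
volume by inverting the coordinate standardization, so that running the
standardization + morphometrics pipeline recovers the ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .coords import VolumeFrame, fit_volume_frame, rotate_z
from .skeleton import Compartment, SkeletonGraph

__all__ = [
    "SyntheticNeuronSpec",
    "SyntheticVolumeSpec",
    "InfeasibleSpecError",
    "generate_synthetic_neuron",
    "make_volume_frame",
    "inverse_standardize",
    "random_feasible_spec",
    "generate_cohort",
]

TUFT_CLASSES = ("atufted", "small_tufted", "tufted")
_TUFT_ZONE_DEPTH = 120.0   # μm below pia a tufted apical must reach
_OBLIQUE_LENGTH = 15.0     # μm, horizontal side branches
_NODE_SPACING = 1.0        # μm


class InfeasibleSpecError(ValueError):
    """Requested descriptor combination has no realizable geometry."""


@dataclass(frozen=True)
class SyntheticNeuronSpec:
    """Ground-truth descriptor set for one synthetic neuron (μm)."""

    soma_position: tuple[float, float, float]
    apical_total_length: float
    apical_width: float
    tuft_class: str
    basal_total_length: float
    basal_bias: float
    oblique_count: int
    height: float
    seed: int = 0

    def __post_init__(self):
        if self.tuft_class not in TUFT_CLASSES:
            raise ValueError(f"unknown tuft_class {self.tuft_class!r}")
        for name in ("apical_total_length", "apical_width",
                     "basal_total_length", "height"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.oblique_count < 0:
            raise ValueError("oblique_count must be nonnegative")
        if self.height < abs(self.basal_bias):
            raise ValueError("height must be at least |basal_bias|")

    def ground_truth(self) -> dict:
        return {
            "soma_depth": self.soma_position[1],
            "height": self.height,
            "total_apical_length": self.apical_total_length,
            "apical_width": self.apical_width,
            "total_basal_length": self.basal_total_length,
            "basal_bias": self.basal_bias,
        }


@dataclass(frozen=True)
class SyntheticVolumeSpec:
    """A tilted synthetic volume with slanted pia / white-matter planes.

    Plane coefficients are in raw (pre-rotation) coordinates:
    ``y = a*x + b*z + c`` with depth y increasing downward.
    """

    tilt_degrees: float = 3.5
    pia_plane: tuple[float, float, float] = (0.05, 0.02, 0.0)
    wm_plane: tuple[float, float, float] = (0.05, 0.02, 850.0)
    grid_spacing: float = 25.0
    extent: tuple[float, float] = (-500.0, 500.0)

    def landmarks(self) -> pd.DataFrame:
        lo, hi = self.extent
        g = np.arange(lo, hi + self.grid_spacing / 2, self.grid_spacing)
        X, Z = np.meshgrid(g, g)
        x, z = X.ravel(), Z.ravel()
        ap, bp, cp = self.pia_plane
        aw, bw, cw = self.wm_plane
        y_pia = ap * x + bp * z + cp
        y_wm = aw * x + bw * z + cw
        if np.any(y_wm <= y_pia):
            raise ValueError("white matter must be deeper than pia everywhere")
        return pd.DataFrame({"x": x, "z": z, "y_pia": y_pia, "y_wm": y_wm})


def make_volume_frame(volume: SyntheticVolumeSpec) -> VolumeFrame:
    return fit_volume_frame(volume.landmarks(), volume.tilt_degrees)


def inverse_standardize(points: np.ndarray, frame: VolumeFrame) -> np.ndarray:
    """Map standardized points back into raw tilted-volume coordinates."""
    pts = np.atleast_2d(np.asarray(points, dtype=float)).copy()
    x, y, z = pts[:, 0], pts[:, 1], pts[:, 2]
    frac = (y - frame.mean_pia_depth) / (frame.mean_wm_depth - frame.mean_pia_depth)
    y_raw_rot = frame.pia_depth_at(x, z) + frac * (
        frame.wm_depth_at(x, z) - frame.pia_depth_at(x, z)
    )
    pts[:, 1] = y_raw_rot
    return rotate_z(pts, -frame.rotation_degrees)


def _subdivide(start, end, spacing=_NODE_SPACING):
    """Interior+end points of a straight segment at ~spacing μm."""
    start = np.asarray(start, float)
    end = np.asarray(end, float)
    length = float(np.linalg.norm(end - start))
    n = max(1, int(np.ceil(length / spacing)))
    ts = np.arange(1, n + 1) / n
    return start + ts[:, None] * (end - start)


class _Builder:
    def __init__(self, soma, rng):
        self.pos = [np.asarray(soma, float)]
        self.comp = [int(Compartment.SOMA)]
        self.parent = [-1]
        self.rng = rng

    def chain(self, start_idx, end, compartment) -> int:
        pts = _subdivide(self.pos[start_idx], end)
        parent = start_idx
        for p in pts:
            self.pos.append(p)
            self.comp.append(int(compartment))
            self.parent.append(parent)
            parent = len(self.pos) - 1
        return parent

    def nearest_on(self, compartment, depth) -> int:
        idx = [k for k, c in enumerate(self.comp) if c == compartment]
        ys = np.array([self.pos[k][1] for k in idx])
        return idx[int(np.argmin(np.abs(ys - depth)))]

    def graph(self, meta=None) -> SkeletonGraph:
        n = len(self.pos)
        ids = np.arange(1, n + 1)
        parents = np.array(
            [-1 if p == -1 else p + 1 for p in self.parent], dtype=int
        )
        return SkeletonGraph(
            ids=ids,
            positions=np.asarray(self.pos),
            radii=np.full(n, np.nan),
            compartments=np.asarray(self.comp),
            parents=parents,
            meta=meta or {},
        )


def generate_synthetic_neuron(
    spec: SyntheticNeuronSpec,
    volume: Optional[SyntheticVolumeSpec | VolumeFrame] = None,
) -> SkeletonGraph:
    """Build the skeleton; positions are standardized (pia-at-zero) unless a
    volume is given, in which case they are mapped into raw tilted coordinates.
    """
    sx, sy, sz = spec.soma_position
    if sy <= 0:
        raise InfeasibleSpecError("soma must lie below the pia (depth > 0)")
    W = spec.apical_width
    La = spec.apical_total_length
    trunk = La - W
    if trunk < 0:
        raise InfeasibleSpecError(
            "apical_total_length shorter than the requested apical width"
        )
    y_top = sy - trunk
    if y_top < 0:
        raise InfeasibleSpecError(
            "apical longer than the soma-to-pia distance; trunk would leave "
            "the volume above the pia"
        )
    if spec.tuft_class != "atufted" and y_top > _TUFT_ZONE_DEPTH:
        raise InfeasibleSpecError(
            f"tuft_class={spec.tuft_class!r} requires the apical to reach "
            f"within {_TUFT_ZONE_DEPTH:.0f} μm of the pia (terminates at "
            f"{y_top:.0f} μm)"
        )
    y_bottom = y_top + spec.height
    if y_bottom < sy:
        raise InfeasibleSpecError(
            "height smaller than the apical span; no node can be deepest"
        )

    # basal geometry: two straight segments from the soma solving exactly for
    # total length and the length-weighted center-of-mass depth offset
    Lb = spec.basal_total_length
    dA = y_bottom - sy                      # deep segment pins the height
    lA = max(1.25 * dA, 0.15 * Lb) if Lb > 0 else 0.0
    if Lb > 0:
        if lA >= Lb:
            raise InfeasibleSpecError(
                "basal_total_length too small for the requested height"
            )
        lB = Lb - lA
        dB = (2.0 * Lb * spec.basal_bias - lA * dA) / lB
        if abs(dB) > lB:
            raise InfeasibleSpecError(
                "basal_bias unreachable with the requested basal length"
            )
        if dB > dA:
            raise InfeasibleSpecError(
                "basal_bias would push a basal node below the height extent"
            )
        if sy + dB < y_top:
            raise InfeasibleSpecError(
                "basal_bias would push a basal node above the apical top"
            )

    rng = np.random.default_rng(spec.seed)
    b = _Builder((sx, sy, sz), rng)

    # apical trunk + tuft arms
    if La > 0:
        top = b.chain(0, (sx, y_top, sz), Compartment.APICAL)
        if W > 0:
            b.chain(top, (sx - W / 2, y_top, sz), Compartment.APICAL)
            b.chain(top, (sx + W / 2, y_top, sz), Compartment.APICAL)

    # basal segments
    if Lb > 0:
        ax = np.sqrt(max(lA**2 - dA**2, 0.0))
        b.chain(0, (sx + ax, sy + dA, sz), Compartment.BASAL)
        bx = np.sqrt(max(lB**2 - dB**2, 0.0))
        b.chain(0, (sx - bx / np.sqrt(2), sy + dB, sz + bx / np.sqrt(2)),
                Compartment.BASAL)
    elif spec.height > trunk:
        raise InfeasibleSpecError("height exceeds apical span but no basal tree")

    # horizontal obliques off the trunk (no effect on the six descriptors)
    if spec.oblique_count > 0:
        if trunk < 10:
            raise InfeasibleSpecError("trunk too short to host obliques")
        depths = np.linspace(y_top + 3, sy - 3, spec.oblique_count + 2)[1:-1]
        for i, dep in enumerate(depths):
            anchor = b.nearest_on(Compartment.APICAL, dep)
            sign = 1 if i % 2 == 0 else -1
            y_anchor = b.pos[anchor][1]
            b.chain(anchor, (sx, y_anchor, sz + sign * _OBLIQUE_LENGTH),
                    Compartment.OBLIQUE)

    graph = b.graph(meta={"spec": spec})
    if volume is not None:
        frame = volume if isinstance(volume, VolumeFrame) else make_volume_frame(volume)
        raw = graph.positions.copy()
        raw[:, 1] += frame.mean_pia_depth  # pia-zeroed -> frame depth
        graph.positions = inverse_standardize(raw, frame)
        graph.meta["frame"] = frame
    return graph


def random_feasible_spec(rng: np.random.Generator,
                         tuft_class: Optional[str] = None,
                         soma_depth: Optional[float] = None,
                         apical_width: Optional[float] = None) -> SyntheticNeuronSpec:
    """Draw one feasible descriptor set from realistic cortical ranges."""
    for _ in range(200):
        tc = tuft_class or TUFT_CLASSES[rng.integers(3)]
        sy = soma_depth if soma_depth is not None else float(rng.uniform(250, 650))
        if tc == "tufted":
            W = float(rng.uniform(120, 300))
            y_top = float(rng.uniform(5, 60))
        elif tc == "small_tufted":
            W = float(rng.uniform(40, 120))
            y_top = float(rng.uniform(5, 80))
        else:
            W = float(rng.uniform(5, 40))
            y_top = float(rng.uniform(125, min(250.0, sy - 60)))
        if apical_width is not None:
            W = apical_width
        La = (sy - y_top) + W
        bias = float(rng.uniform(-40, 60))
        dA = max(40.0, 2.2 * abs(bias)) + float(rng.uniform(10, 120))
        height = (sy + dA) - y_top
        Lb = float(rng.uniform(900, 2500))
        spec = SyntheticNeuronSpec(
            soma_position=(float(rng.uniform(-400, 400)), sy,
                           float(rng.uniform(-400, 400))),
            apical_total_length=La,
            apical_width=W,
            tuft_class=tc,
            basal_total_length=Lb,
            basal_bias=bias,
            oblique_count=int(rng.integers(0, 6)),
            height=height,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        try:
            generate_synthetic_neuron(spec)  # feasibility probe
        except InfeasibleSpecError:
            continue
        return spec
    raise RuntimeError("could not draw a feasible spec (ranges too tight)")


def generate_cohort(
    n: int,
    seed: int,
    volume: Optional[SyntheticVolumeSpec] = None,
    depth_width_slope: float = 0.0,
) -> tuple[list[SyntheticNeuronSpec], list[SkeletonGraph]]:
    """Draw ``n`` feasible specs and their skeletons.

    ``depth_width_slope`` < 0 injects a depth-decreasing apical-width trend
    (width = 300 + slope * soma_depth + noise, clipped to feasible values),
    emulating the superficial-layer widening of apical tufts.
    """
    rng = np.random.default_rng(seed)
    frame = make_volume_frame(volume) if volume is not None else None
    specs, graphs = [], []
    for _ in range(n):
        if depth_width_slope != 0.0:
            sy = float(rng.uniform(250, 650))
            w = 300.0 + depth_width_slope * sy + float(rng.normal(0, 10))
            w = float(np.clip(w, 10, 320))
            tc = "tufted" if w >= 120 else ("small_tufted" if w >= 40 else "atufted")
            spec = random_feasible_spec(rng, tuft_class=tc, soma_depth=sy,
                                        apical_width=w)
        else:
            spec = random_feasible_spec(rng)
        specs.append(spec)
        graphs.append(generate_synthetic_neuron(spec, volume=frame))
    return specs, graphs
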