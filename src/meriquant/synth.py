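"""Seeded synthetic-data generators for the whole analysis pipeline.

Real inputs are per-cell 3D geometry tables exported from segmented
confocal stacks (MorphoGraphX / 3D Cell Atlas style), lineage-tracked
two-time-point tables, displacement tracks from 2D time-lapse movies, and
2D cross-section cell meshes. The generators here emulate the statistical
structure of those inputs — per-tissue geometry distributions on
transformed scales with root-level random intercepts, a two-zone
(meristem/elongation) cell-length mixture, near-exponential displacement
along the meristem, division-aware growth between two time points, and
concentric root cross-section anatomy — so every downstream module can be
exercised and validated without microscopy data.

All generators are deterministic for a fixed configuration and seed: each
call owns a single :func:`numpy.random.default_rng` stream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Sequence, Tuple

import numpy as np
import pandas as pd

from .mesh import (
    CORTEX_WALL,
    EPIDERMAL_OTHER,
    INNER_ENDODERMAL,
    OUTER_ENDODERMAL,
    OUTER_EPIDERMAL,
    PERICYCLE_STELE,
    CrossSectionMesh,
    GeometryError,
)

TISSUES_3D = (
    "epidermis_nonhair",
    "epidermis_hair",
    "cortex",
    "endodermis",
    "pericycle",
)

#: length × width × depth → volume proxy (cells are rounded cuboids)
SHAPE_FACTOR = 0.85
#: cuboid surface 2(LW+LD+WD) → surface-area proxy
SURFACE_FACTOR = 0.9


class ConfigurationError(ValueError):
    """A generator configuration violates its invariants."""


class GenerationError(RuntimeError):
    """Generated output failed a structural validity check."""


# ---------------------------------------------------------------------------
# 3D geometry tables
# ---------------------------------------------------------------------------

def _default_baseline() -> Dict[str, Dict[str, Tuple[float, float]]]:
    """Per-tissue (base, trend-in-sqrt-distance) on the transformed scales.

    Length and depth are modelled on the log scale, width on the raw µm
    scale; meristematic cells are ~5–10 µm long while elongation-zone
    cells reach tens of µm, and the radial parameters grow gradually with
    distance from the quiescent centre while length is the least
    distance-dependent parameter.
    """
    base = {}
    widths = {
        "epidermis_nonhair": 14.0,
        "epidermis_hair": 13.0,
        "cortex": 17.0,
        "endodermis": 12.0,
        "pericycle": 8.0,
    }
    depths = {
        "epidermis_nonhair": 2.35,
        "epidermis_hair": 2.30,
        "cortex": 2.55,
        "endodermis": 2.20,
        "pericycle": 1.95,
    }
    for tissue in TISSUES_3D:
        base[tissue] = {
            "log_length_short": (np.log(6.5), 0.012),
            "log_length_long": (np.log(40.0), 0.055),
            "log_depth": (depths[tissue], 0.035),
            "width": (widths[tissue], 0.30),
        }
    return base


def _default_treatment_effects() -> Dict[str, Dict[str, float]]:
    """Additive condition shifts on the transformed scales.

    Raising BR signalling (BL treatment) lengthens cells and thins their
    radial axes; losing the receptor (bri1, low BR) does the opposite.
    """
    return {
        "WT": {"log_length": 0.0, "log_depth": 0.0, "width": 0.0},
        "bri1": {"log_length": -0.20, "log_depth": 0.15, "width": 2.5},
        "BL": {"log_length": 0.25, "log_depth": -0.15, "width": -2.0},
    }


@dataclass
class ZoneMixture:
    """Two-component cell-length mixture along the root axis.

    ``weight_short`` is the marginal probability of the short (meristem)
    component under the uniform distance distribution; the probability of
    the short component decays logistically with distance from the QC over
    ``transition_width`` µm (0 gives a sharp deterministic cut).
    """

    weight_short: float = 0.85
    transition_width: float = 15.0

    def p_short(self, distance: np.ndarray, d_lo: float, d_hi: float) -> np.ndarray:
        mid = d_lo + (d_hi - d_lo) * self.weight_short
        if self.transition_width == 0:
            return (distance <= mid).astype(float)
        return 1.0 / (1.0 + np.exp((distance - mid) / self.transition_width))


@dataclass
class SynthGeometryConfig:
    """Configuration of the per-cell 3D geometry generator."""

    treatments: Sequence[str] = ("WT", "bri1", "BL")
    roots_per_treatment: int = 4
    cells_per_root_per_tissue: int = 100
    tissues: Sequence[str] = TISSUES_3D
    baseline_geometry: Dict = field(default_factory=_default_baseline)
    treatment_effects: Dict = field(default_factory=_default_treatment_effects)
    root_sd: Dict[str, float] = field(
        default_factory=lambda: {"log_length": 0.08, "log_depth": 0.06, "width": 0.8}
    )
    residual_sd: Dict[str, float] = field(
        default_factory=lambda: {"log_length": 0.18, "log_depth": 0.15, "width": 2.0}
    )
    zone_mixture: ZoneMixture = field(default_factory=ZoneMixture)
    distance_range: Tuple[float, float] = (4.0, 200.0)
    shape_factor: float = SHAPE_FACTOR
    surface_factor: float = SURFACE_FACTOR
    seed: int = 0

    def validate(self) -> None:
        if self.roots_per_treatment <= 0 or self.cells_per_root_per_tissue <= 0:
            raise ConfigurationError("cell and root counts must be positive")
        if not 0 < self.zone_mixture.weight_short < 1:
            raise ConfigurationError("mixing weight must be in (0, 1)")
        if self.zone_mixture.transition_width < 0:
            raise ConfigurationError("transition width must be >= 0")
        if not 0 < self.shape_factor <= 1:
            raise ConfigurationError("shape factor must be in (0, 1]")
        for sd in (*self.root_sd.values(), *self.residual_sd.values()):
            if sd < 0:
                raise ConfigurationError("standard deviations must be >= 0")
        for tissue in self.tissues:
            b = self.baseline_geometry[tissue]
            if b["log_length_short"][0] >= b["log_length_long"][0]:
                raise ConfigurationError(
                    "short-component mean length must be below the long component"
                )
            if b["width"][0] <= 0:
                raise ConfigurationError("baseline width must be positive")


def generate_geometry_table(config: SynthGeometryConfig) -> pd.DataFrame:
    """Draw a per-cell 3D geometry table.

    One row per cell with columns ``cell_id, root_id, treatment, tissue,
    distance_qc, length, width, depth, surface_area, volume`` plus the
    hidden ground-truth ``true_zone`` label used to validate the zone
    classifier. Volume and surface area follow a cuboid-like proxy so they
    can be recomputed from the linear dimensions in tests.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    d_lo, d_hi = config.distance_range
    rows = []
    cell_id = 0
    for treatment in config.treatments:
        effects = config.treatment_effects.get(treatment, {})
        for r in range(config.roots_per_treatment):
            root_id = f"{treatment}_root{r}"
            intercept = {
                p: rng.normal(0.0, config.root_sd.get(p, 0.0))
                for p in ("log_length", "log_depth", "width")
            }
            for tissue in config.tissues:
                b = config.baseline_geometry[tissue]
                n = config.cells_per_root_per_tissue
                d = rng.uniform(d_lo, d_hi, n)
                p_short = config.zone_mixture.p_short(d, d_lo, d_hi)
                short = rng.uniform(size=n) < p_short
                sq = np.sqrt(d)
                base_l = np.where(
                    short,
                    b["log_length_short"][0] + b["log_length_short"][1] * sq,
                    b["log_length_long"][0] + b["log_length_long"][1] * sq,
                )
                log_l = (
                    base_l
                    + effects.get("log_length", 0.0)
                    + intercept["log_length"]
                    + rng.normal(0.0, config.residual_sd["log_length"], n)
                )
                log_d = (
                    b["log_depth"][0]
                    + b["log_depth"][1] * sq
                    + effects.get("log_depth", 0.0)
                    + intercept["log_depth"]
                    + rng.normal(0.0, config.residual_sd["log_depth"], n)
                )
                w = (
                    b["width"][0]
                    + b["width"][1] * sq
                    + effects.get("width", 0.0)
                    + intercept["width"]
                    + rng.normal(0.0, config.residual_sd["width"], n)
                )
                w = np.maximum(w, 0.5)  # widths stay physical under noise
                length = np.exp(log_l)
                depth = np.exp(log_d)
                volume = config.shape_factor * length * w * depth
                surface = config.surface_factor * 2.0 * (
                    length * w + length * depth + w * depth
                )
                for i in range(n):
                    rows.append(
                        (
                            f"c{cell_id + i}",
                            root_id,
                            treatment,
                            tissue,
                            d[i],
                            length[i],
                            w[i],
                            depth[i],
                            surface[i],
                            volume[i],
                            "meristem" if short[i] else "elongation",
                        )
                    )
                cell_id += n
    return pd.DataFrame(
        rows,
        columns=[
            "cell_id",
            "root_id",
            "treatment",
            "tissue",
            "distance_qc",
            "length",
            "width",
            "depth",
            "surface_area",
            "volume",
            "true_zone",
        ],
    )


# ---------------------------------------------------------------------------
# Displacement tracks
# ---------------------------------------------------------------------------

@dataclass
class SynthTrackConfig:
    """Configuration of the time-lapse displacement-track generator.

    The underlying velocity field is v(x) = relative_rate × (intercept +
    slope·x) with x the distance from the QC in µm; tracks integrate it
    exactly and add observation noise per sampled time point. Defaults
    mirror a 6 h movie sampled every 30 min with cells displacing a few
    µm/h, faster away from the QC.
    """

    velocity_intercept: float = 0.0  # µm/h
    velocity_slope: float = 0.04  # 1/h
    relative_rate_per_treatment: Dict[str, float] = field(
        default_factory=lambda: {"WT": 1.0, "bri1": 0.57, "BL": 3.0}
    )
    sampling_interval: float = 0.5  # h
    duration: float = 6.0  # h
    track_noise_sd: float = 0.2  # µm
    n_cells: int = 30  # per condition
    start_range: Tuple[float, float] = (8.0, 70.0)
    seed: int = 0

    def validate(self) -> None:
        a, b = self.velocity_intercept, self.velocity_slope
        for r in self.relative_rate_per_treatment.values():
            if r < 0:
                raise ConfigurationError("relative rates must be >= 0")
            if min(r * (a + b * x) for x in (0.0, 100.0)) < 0:
                raise ConfigurationError("velocity must be non-negative on [0, 100] µm")
        if self.duration / self.sampling_interval < 2:
            raise ConfigurationError("need at least 3 observations per track")
        if self.n_cells <= 0:
            raise ConfigurationError("n_cells must be positive")
        if self.track_noise_sd < 0:
            raise ConfigurationError("noise sd must be >= 0")


def _integrate_position(x0, a, b, r, t):
    """Exact solution of dx/dt = r(a + bx) from x0, vectorized over t."""
    if b == 0.0 or r == 0.0:
        return x0 + r * a * t
    return (x0 + a / b) * np.exp(r * b * t) - a / b


def generate_tracks(config: SynthTrackConfig) -> pd.DataFrame:
    """Draw displacement tracks, one row per (cell, time point).

    Columns: ``cell_id, condition, time_h, distance_qc``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    times = np.arange(0.0, config.duration + 1e-9, config.sampling_interval)
    rows = []
    for cond, rate in config.relative_rate_per_treatment.items():
        x0 = rng.uniform(*config.start_range, config.n_cells)
        for i in range(config.n_cells):
            x = _integrate_position(
                x0[i], config.velocity_intercept, config.velocity_slope, rate, times
            )
            x_obs = x + rng.normal(0.0, config.track_noise_sd, times.size)
            for t, xo in zip(times, x_obs):
                rows.append((f"{cond}_c{i}", cond, t, xo))
    return pd.DataFrame(rows, columns=["cell_id", "condition", "time_h", "distance_qc"])


# ---------------------------------------------------------------------------
# Lineage-tracked 4D pairs
# ---------------------------------------------------------------------------

@dataclass
class Synth4DConfig:
    """Configuration of the two-time-point lineage-pair generator.

    ``rates`` are true per-hour growth rates (length, width, depth) in
    µm/h per condition; t₁ geometry is t₀ plus rate×Δt plus noise, and a
    dividing cell is replaced by two daughters whose lengths and volumes
    sum to the grown value while depth and width are carried per daughter.
    """

    conditions: Sequence[str] = ("WT", "bri1", "BL")
    n_cells_per_condition: int = 60
    tissue: str = "epidermis_nonhair"
    rates: Dict[str, Tuple[float, float, float]] = field(
        default_factory=lambda: {
            "WT": (0.50, 0.05, 0.05),
            "bri1": (0.28, 0.03, 0.08),
            "BL": (1.50, 0.02, 0.05),
        }
    )
    division_probability: float = 0.3
    dt: float = 12.0  # h
    noise_sd: float = 0.05  # µm, on each linear dimension at t1
    distance_range: Tuple[float, float] = (4.0, 60.0)
    displacement_slope: float = 0.03  # 1/h, exponential drift of position
    baseline: Tuple[float, float, float] = (8.0, 14.0, 10.0)  # L, W, D µm at t0
    shape_factor: float = SHAPE_FACTOR
    seed: int = 0

    def validate(self) -> None:
        if self.dt <= 0:
            raise ConfigurationError("dt must be positive")
        if not 0 <= self.division_probability <= 1:
            raise ConfigurationError("division probability must be in [0, 1]")
        if self.n_cells_per_condition <= 0:
            raise ConfigurationError("n_cells_per_condition must be positive")


def generate_pairs_4d(config: Synth4DConfig) -> pd.DataFrame:
    """Draw a raw lineage-pair table, one row per daughter cell.

    Columns: ``cell_id, condition, tissue, dt, distance_qc_t0,
    distance_qc_t1, length_t0, width_t0, depth_t0, volume_t0, daughter_id,
    length_t1, width_t1, depth_t1, volume_t1``. Undivided cells emit a
    single daughter row.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    rows = []
    L0b, W0b, D0b = config.baseline
    for cond in config.conditions:
        rL, rW, rD = config.rates[cond]
        for i in range(config.n_cells_per_condition):
            cid = f"{cond}_p{i}"
            d0 = rng.uniform(*config.distance_range)
            d1 = d0 * np.exp(config.displacement_slope * config.dt)
            L0 = max(L0b + rng.normal(0, 1.0), 2.0)
            W0 = max(W0b + rng.normal(0, 1.5), 2.0)
            D0 = max(D0b + rng.normal(0, 1.5), 2.0)
            V0 = config.shape_factor * L0 * W0 * D0
            L1 = L0 + rL * config.dt + rng.normal(0, config.noise_sd)
            W1 = W0 + rW * config.dt + rng.normal(0, config.noise_sd)
            D1 = D0 + rD * config.dt + rng.normal(0, config.noise_sd)
            V1 = config.shape_factor * L1 * W1 * D1
            divided = rng.uniform() < config.division_probability
            if divided:
                f = rng.uniform(0.4, 0.6)
                daughters = [
                    (f * L1, W1, D1, f * V1),
                    ((1 - f) * L1, W1, D1, (1 - f) * V1),
                ]
            else:
                daughters = [(L1, W1, D1, V1)]
            for j, (l, w, d, v) in enumerate(daughters):
                rows.append(
                    (
                        cid,
                        cond,
                        config.tissue,
                        config.dt,
                        d0,
                        d1,
                        L0,
                        W0,
                        D0,
                        V0,
                        f"{cid}_d{j}",
                        l,
                        w,
                        d,
                        v,
                    )
                )
    return pd.DataFrame(
        rows,
        columns=[
            "cell_id",
            "condition",
            "tissue",
            "dt",
            "distance_qc_t0",
            "distance_qc_t1",
            "length_t0",
            "width_t0",
            "depth_t0",
            "volume_t0",
            "daughter_id",
            "length_t1",
            "width_t1",
            "depth_t1",
            "volume_t1",
        ],
    )


# ---------------------------------------------------------------------------
# Cross-section meshes
# ---------------------------------------------------------------------------

@dataclass
class SynthMeshConfig:
    """Configuration of the concentric cross-section mesh generator.

    Default counts follow canonical Arabidopsis root anatomy at the 8 µm
    section: 20 epidermis, 8 cortex, 8 endodermis, 12 pericycle and 18
    stele cells, with ring boundary radii in µm.
    """

    n_epidermis: int = 20
    n_cortex: int = 8
    n_endodermis: int = 8
    n_pericycle: int = 12
    n_stele: int = 18
    radii: Tuple[float, ...] = (18.0, 24.0, 31.0, 40.0, 50.0)
    jitter_sd: float = 0.0
    seed: int = 0

    def counts(self) -> Tuple[int, ...]:
        return (
            self.n_stele,
            self.n_pericycle,
            self.n_endodermis,
            self.n_cortex,
            self.n_epidermis,
        )

    def validate(self) -> None:
        if self.n_stele < 3:
            raise ConfigurationError("need at least 3 stele cells")
        if min(self.counts()[1:]) < 2:
            raise ConfigurationError("each ring needs at least 2 cells")
        if len(self.radii) != 5 or np.any(np.diff(self.radii) <= 0) or self.radii[0] <= 0:
            raise ConfigurationError("radii must be 5 strictly increasing positive values")
        if self.jitter_sd < 0:
            raise ConfigurationError("jitter sd must be >= 0")


_RING_TISSUES = ("stele", "pericycle", "endodermis", "cortex", "epidermis")


def _classify_wall(tissues, is_boundary) -> str:
    """Wall class from the tissues of the incident cells.

    Precedence: the outermost epidermal surface, then any epidermal wall,
    then the endodermal interfaces (cortex side = outer, pericycle/stele
    side = inner; radial endodermis–endodermis walls join the outer
    class), then cortex walls, with everything inside the pericycle in the
    pericycle–stele class.
    """
    s = set(tissues)
    if "epidermis" in s:
        return OUTER_EPIDERMAL if is_boundary else EPIDERMAL_OTHER
    if "endodermis" in s:
        if "pericycle" in s or "stele" in s:
            return INNER_ENDODERMAL
        return OUTER_ENDODERMAL
    if "cortex" in s:
        return CORTEX_WALL
    return PERICYCLE_STELE


def generate_mesh(config: SynthMeshConfig) -> CrossSectionMesh:
    """Build a watertight concentric cross-section mesh.

    The stele is tessellated as wedges meeting at a central vertex; each
    outer ring is a band of annular-sector cells. Ring boundary circles
    carry the union of both adjacent rings' sector angles so every wall is
    shared exactly. Vertex positions can be jittered; the result is
    validated and a :class:`GenerationError` is raised if jitter produced
    a degenerate polygon.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    counts = config.counts()
    radii = list(config.radii)

    ring_angles = []
    for i, n in enumerate(counts):
        offset = (i % 2) * np.pi / n  # stagger alternate rings
        ring_angles.append((offset + 2.0 * np.pi * np.arange(n) / n) % (2.0 * np.pi))

    # circle i sits at radii[i]; it bounds ring i (inside) and ring i+1.
    # The outermost circle gains midpoint vertices so the boundary polygon
    # tracks the circle closely (area deficit stays well under 1%).
    circle_angles = []
    for i in range(5):
        if i == 4:
            n = counts[4]
            angs = np.concatenate(
                [ring_angles[4], ring_angles[4] + np.pi / n]
            )
        else:
            angs = np.concatenate([ring_angles[i], ring_angles[i + 1]])
        angs = np.unique(np.round(np.sort(angs % (2.0 * np.pi)), 12))
        circle_angles.append(angs)

    vertices = [(0.0, 0.0)]  # central vertex of the stele wedges
    circle_vid = []
    for i, angs in enumerate(circle_angles):
        vids = {}
        for a in angs:
            vids[a] = len(vertices)
            vertices.append((radii[i] * np.cos(a), radii[i] * np.sin(a)))
        circle_vid.append(vids)
    vertices = np.array(vertices)
    if config.jitter_sd > 0:
        vertices[1:] += rng.normal(0.0, config.jitter_sd, (len(vertices) - 1, 2))

    def arc(circle: int, t0: float, t1: float) -> list:
        """Vertex ids on a circle from angle t0 to t1, CCW inclusive."""
        angs = np.array(sorted(circle_vid[circle]))
        span = (t1 - t0) % (2.0 * np.pi)
        rel = (angs - t0) % (2.0 * np.pi)
        rel = np.where(rel > 2.0 * np.pi - 1e-6, 0.0, rel)  # snap t0 itself
        sel = angs[rel <= span + 1e-6]
        order = np.argsort(rel[rel <= span + 1e-6])
        return [circle_vid[circle][a] for a in sel[order]]

    cells, tissues = [], []
    for ri, (tissue, n) in enumerate(zip(_RING_TISSUES, counts)):
        th = ring_angles[ri]
        for k in range(n):
            t0, t1 = th[k], th[(k + 1) % n]
            if ri == 0:
                loop = [0] + arc(0, t0, t1)
            else:
                outer = arc(ri, t0, t1)
                inner = arc(ri - 1, t0, t1)[::-1]
                loop = outer + inner
            cells.append(np.array(loop, dtype=np.intp))
            tissues.append(tissue)

    # derive walls + classes from the cell loops
    edge_cells: Dict[Tuple[int, int], list] = {}
    for ci, loop in enumerate(cells):
        for a, b in zip(loop, np.roll(loop, -1)):
            edge_cells.setdefault((min(a, b), max(a, b)), []).append(ci)
    walls, classes = [], []
    for (a, b), inc in edge_cells.items():
        walls.append((a, b))
        classes.append(_classify_wall([tissues[c] for c in inc], len(inc) == 1))

    mesh = CrossSectionMesh(
        vertices,
        np.array(walls, dtype=np.intp),
        np.array(classes, dtype=object),
        np.zeros(len(walls)),
        cells,
        tissues,
    )
    mesh.rest_length = mesh.wall_lengths()
    try:
        mesh.validate()
    except GeometryError as exc:
        raise GenerationError(f"generated mesh is degenerate: {exc}") from exc
    return mesh
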