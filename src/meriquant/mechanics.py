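"""Mass-spring mechanics of a growing root cross section.

Walls are linear springs whose tension is stiffness × strain with strain
(l − l₀)/l₀; every cell exerts its turgor pressure on its walls (outward
force pressure × wall length, split equally between the wall's endpoint
vertices, netted over the two adjacent cells). These forces are exactly
the negative gradient of the potential

    E = Σ_walls ½ k ε² l₀  −  Σ_cells P · A,

so mechanical quasi-equilibrium is found by monotone energy descent on
the vertex positions (adaptive Barzilai–Borwein gradient steps with
backtracking) until the largest vertex force drops below tolerance.
Growth is stress relaxation: each growth step lengthens every wall's rest
length in proportion to its super-threshold strain and the extensibility
of its adjacent cells, after which the section is re-relaxed. Because
growth depends only on strain ratios, scaling all stiffnesses and
pressures together leaves the trajectory unchanged.

The stiffness-fitting procedure mirrors the genotype analyses: wall
classes are split into an inner group (inner-endodermal and
pericycle–stele walls) and an outer group (everything else), and two
multipliers on the group stiffnesses are optimized (Nelder–Mead in log
space) so that the simulated inner/outer tissue-area extensions at a
prescribed growth-step budget match target extensions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
from scipy import optimize

from .mesh import (
    INNER_ENDODERMAL,
    INNER_TISSUES,
    OUTER_TISSUES,
    PERICYCLE_STELE,
    WALL_CLASSES,
    CrossSectionMesh,
    tissue_areas,
)

#: wall classes whose stiffness the inner multiplier scales
INNER_WALL_CLASSES = frozenset({INNER_ENDODERMAL, PERICYCLE_STELE})


class SimulationError(RuntimeError):
    """Relaxation failed to converge or growth stalled."""


@dataclass
class SimParams:
    """Mechanical and growth parameters of a simulation.

    ``stiffness`` maps wall classes to spring stiffness (force per unit
    strain), ``pressure`` and ``extensibility`` map tissues to turgor
    pressure (force/length) and to the per-step conversion of
    super-threshold strain into rest-length growth (1/step). Units are
    arbitrary but joint: scaling all stiffnesses and pressures by the
    same factor changes nothing.
    """

    stiffness: Dict[str, float] = field(
        default_factory=lambda: {c: 500.0 for c in WALL_CLASSES}
    )
    extensibility: Dict[str, float] = field(
        default_factory=lambda: {t: 0.05 for t in (*INNER_TISSUES, *OUTER_TISSUES)}
    )
    pressure: Dict[str, float] = field(
        default_factory=lambda: {t: 1.0 for t in (*INNER_TISSUES, *OUTER_TISSUES)}
    )
    growth_threshold: float = 0.0  # strain below which walls do not grow
    force_tol: float = 0.05  # max residual vertex force at equilibrium
    max_relax_iter: int = 50000
    growth_step: float = 1.0  # multiplier on the per-step rest-length gain
    max_growth_steps: int = 5000

    def validate(self) -> None:
        if any(k <= 0 for k in self.stiffness.values()):
            raise ValueError("stiffness must be positive")
        if self.growth_threshold < 0 or self.force_tol <= 0:
            raise ValueError("threshold must be >= 0 and tolerance > 0")

    def scaled_stiffness(
        self, inner: float, outer: float, inner_classes=INNER_WALL_CLASSES
    ) -> "SimParams":
        """Copy of the parameters with group-wise stiffness multipliers."""
        stiff = {
            c: k * (inner if c in inner_classes else outer)
            for c, k in self.stiffness.items()
        }
        return SimParams(
            stiffness=stiff,
            extensibility=dict(self.extensibility),
            pressure=dict(self.pressure),
            growth_threshold=self.growth_threshold,
            force_tol=self.force_tol,
            max_relax_iter=self.max_relax_iter,
            growth_step=self.growth_step,
            max_growth_steps=self.max_growth_steps,
        )


def dual_ring_params(
    base_stiffness: float = 500.0,
    pressure: float = 1.0,
    growth_step: float = 2.0,
    **kwargs,
) -> SimParams:
    """WT-calibrated dual-ring parameters.

    Epidermal walls and both endodermal wall layers are stiffened
    relative to the base and the innermost pericycle/stele walls are
    softened — the two stiff rings (outer epidermis, endodermis) that
    dominate radial growth control. Because with uniform turgor the hoop
    tension decays towards the axis, stiffness alone cannot make the
    inner tissues outgrow the outer ones; extensibility is therefore
    graded, highest in the stele and lowest in the epidermis, so the
    calibrated section reproduces the in-vivo pattern in which the inner
    tissues (stele most of all) gain relatively more area than epidermis
    and cortex.
    """
    stiffness = {
        "outer-epidermal": 4.0 * base_stiffness,
        "epidermal-other": 2.5 * base_stiffness,
        "cortex": 1.0 * base_stiffness,
        "outer-endodermal": 2.0 * base_stiffness,
        "inner-endodermal": 2.0 * base_stiffness,
        "pericycle-stele": 0.4 * base_stiffness,
    }
    extensibility = {
        "stele": 2.0,
        "pericycle": 1.6,
        "endodermis": 1.2,
        "cortex": 0.2,
        "epidermis": 0.1,
    }
    return SimParams(
        stiffness=stiffness,
        extensibility=extensibility,
        pressure={t: pressure for t in (*INNER_TISSUES, *OUTER_TISSUES)},
        growth_step=growth_step,
        **kwargs,
    )


class _System:
    """Flattened index arrays for fast force/energy evaluation."""

    def __init__(self, mesh: CrossSectionMesh, params: SimParams):
        self.mesh = mesh
        self.wi = mesh.walls[:, 0]
        self.wj = mesh.walls[:, 1]
        self.k = np.array([params.stiffness[c] for c in mesh.wall_class])
        # per-wall extensibility = mean of adjacent cells' extensibility
        ext = []
        for inc in mesh.wall_cells():
            ext.append(
                float(
                    np.mean([params.extensibility[mesh.cell_tissue[c]] for c in inc])
                )
            )
        self.wall_ext = np.array(ext)
        # flattened cell edges for pressure forces and areas
        ea, eb, ep, ec = [], [], [], []
        for ci, loop in enumerate(mesh.cells):
            P = params.pressure[mesh.cell_tissue[ci]]
            nxt = np.roll(loop, -1)
            ea.extend(loop)
            eb.extend(nxt)
            ep.extend([P] * len(loop))
            ec.extend([ci] * len(loop))
        self.ea = np.array(ea, dtype=np.intp)
        self.eb = np.array(eb, dtype=np.intp)
        self.ep = np.array(ep)
        self.ecell = np.array(ec, dtype=np.intp)
        self.n_cells = len(mesh.cells)
        self.nv = len(mesh.vertices)
        self.P_cell = np.array(
            [params.pressure[t] for t in mesh.cell_tissue], dtype=float
        )

    def cell_areas(self, V: np.ndarray) -> np.ndarray:
        cross = (
            V[self.ea, 0] * V[self.eb, 1] - V[self.eb, 0] * V[self.ea, 1]
        )
        return 0.5 * np.bincount(self.ecell, weights=cross, minlength=self.n_cells)

    def energy_force(self, V: np.ndarray, l0: np.ndarray):
        d = V[self.wj] - V[self.wi]
        l = np.hypot(d[:, 0], d[:, 1])
        eps = (l - l0) / l0
        E_spring = float(np.sum(0.5 * self.k * eps**2 * l0))
        tension = self.k * eps
        fx = tension * d[:, 0] / l
        fy = tension * d[:, 1] / l
        Fx = np.bincount(self.wi, weights=fx, minlength=self.nv) - np.bincount(
            self.wj, weights=fx, minlength=self.nv
        )
        Fy = np.bincount(self.wi, weights=fy, minlength=self.nv) - np.bincount(
            self.wj, weights=fy, minlength=self.nv
        )
        # pressure: edge (a→b) of a CCW cell pushes both endpoints outward
        # by P/2 · perp(b − a), perp(d) = (d_y, −d_x)
        dx = V[self.eb, 0] - V[self.ea, 0]
        dy = V[self.eb, 1] - V[self.ea, 1]
        px = 0.5 * self.ep * dy
        py = -0.5 * self.ep * dx
        Fx += np.bincount(self.ea, weights=px, minlength=self.nv)
        Fx += np.bincount(self.eb, weights=px, minlength=self.nv)
        Fy += np.bincount(self.ea, weights=py, minlength=self.nv)
        Fy += np.bincount(self.eb, weights=py, minlength=self.nv)
        areas = self.cell_areas(V)
        E = E_spring - float(np.sum(self.P_cell * areas))
        return E, np.column_stack([Fx, Fy])

    def strains(self, V: np.ndarray, l0: np.ndarray) -> np.ndarray:
        d = V[self.wj] - V[self.wi]
        return (np.hypot(d[:, 0], d[:, 1]) - l0) / l0


def total_energy(mesh: CrossSectionMesh, params: SimParams) -> float:
    """Spring energy minus pressure–area work of the current configuration."""
    sys = _System(mesh, params)
    E, _ = sys.energy_force(mesh.vertices, mesh.rest_length)
    return E


def relax(
    mesh: CrossSectionMesh,
    params: SimParams,
    inplace: bool = False,
    _system: Optional[_System] = None,
) -> CrossSectionMesh:
    """Drive the mesh to mechanical quasi-equilibrium.

    Overdamped monotone descent on the total potential: trial steps move
    every vertex along its net force, the step size adapts by a
    Barzilai–Borwein estimate and is halved whenever the energy would
    rise, and iteration stops when the largest vertex force falls below
    ``params.force_tol``. Raises :class:`SimulationError` with the
    residual force when ``max_relax_iter`` is exhausted.
    """
    params.validate()
    out = mesh if inplace else mesh.copy()
    sys = _system if _system is not None else _System(out, params)
    V = out.vertices.copy()
    l0 = out.rest_length
    E, F = sys.energy_force(V, l0)
    kmax = max(params.stiffness.values())
    alpha = 0.1 * float(np.mean(l0)) / kmax
    alpha_max = 100.0 * alpha
    # cap the largest single-iteration vertex move: along tension-free
    # floppy modes (untriangulated, unloaded interior quads) the energy is
    # locally flat and unbounded steps would wander without penalty
    dmax = 0.05 * float(np.mean(l0))
    for _ in range(params.max_relax_iter):
        fmax = float(np.max(np.hypot(F[:, 0], F[:, 1])))
        if fmax < params.force_tol:
            out.vertices = V
            return out
        step = min(alpha, dmax / fmax)
        V_new = V + step * F
        E_new, F_new = sys.energy_force(V_new, l0)
        # the rounding allowance keeps progress near convergence, where
        # the true energy decrease f²·α falls below double precision
        if E_new <= E + 1e-12 * (abs(E) + 1.0):
            s = (V_new - V).ravel()
            y = (F - F_new).ravel()  # gradient difference (g = −F)
            sy = float(s @ y)
            if sy > 0:
                alpha = min(max(float(s @ s) / sy, 1e-4 * alpha), alpha_max)
            else:
                alpha = min(alpha * 1.5, alpha_max)
            V, E, F = V_new, E_new, F_new
        else:
            alpha *= 0.5
            if alpha < 1e-18:
                break
    fmax = float(np.max(np.hypot(F[:, 0], F[:, 1])))
    raise SimulationError(
        f"relaxation did not converge: residual force {fmax:.3g} "
        f"(tolerance {params.force_tol})"
    )


def grow_step(
    mesh: CrossSectionMesh,
    params: SimParams,
    inplace: bool = False,
    _system: Optional[_System] = None,
) -> CrossSectionMesh:
    """One stress-relaxation growth step followed by re-relaxation.

    Every wall's rest length grows by ``growth_step × extensibility ×
    max(0, strain − threshold) × l₀``, with the wall extensibility the
    mean of its adjacent cells' values (boundary walls take their single
    cell's). Walls whose strain is below the threshold are untouched.
    """
    out = mesh if inplace else mesh.copy()
    sys = _system if _system is not None else _System(out, params)
    eps = sys.strains(out.vertices, out.rest_length)
    gain = params.growth_step * sys.wall_ext * np.maximum(
        0.0, eps - params.growth_threshold
    )
    out.rest_length = out.rest_length * (1.0 + gain)
    return relax(out, params, inplace=True, _system=sys)


@dataclass
class SimResult:
    """Outcome of a growth simulation."""

    tissue_initial: Dict[str, float]
    tissue_final: Dict[str, float]
    inner_extension: float  # endodermis+pericycle+stele, final/initial
    outer_extension: float  # epidermis+cortex, final/initial
    steps: int
    area_trajectory: np.ndarray
    final_mesh: CrossSectionMesh

    @property
    def extensions(self) -> Dict[str, float]:
        return {
            t: self.tissue_final[t] / self.tissue_initial[t]
            for t in self.tissue_initial
        }


def _group_areas(areas: Dict[str, float]) -> Tuple[float, float]:
    inner = sum(a for t, a in areas.items() if t in INNER_TISSUES)
    outer = sum(a for t, a in areas.items() if t in OUTER_TISSUES)
    return inner, outer


def simulate_to_area(
    mesh: CrossSectionMesh,
    params: SimParams,
    target_area: Optional[float] = None,
    step_budget: Optional[int] = None,
    target_extension: Optional[float] = None,
) -> SimResult:
    """Relax, then grow until a total-area target or a step budget.

    In area mode the section grows until its total area reaches
    ``target_area`` (the area of the section the tissue is being grown
    towards); ``target_extension`` instead expresses the target as a fold
    change of the relaxed initial area, which makes runs with different
    parameter sets comparable (their relaxed initial states differ); in
    time mode exactly ``step_budget`` growth steps are taken. Reports
    per-tissue initial/final areas and the inner/outer group extensions.
    Raises :class:`SimulationError` if growth stalls before an area
    target.
    """
    n_modes = sum(x is not None for x in (target_area, step_budget, target_extension))
    if n_modes != 1:
        raise ValueError(
            "give exactly one of target_area, step_budget or target_extension"
        )
    work = mesh.copy()
    sys = _System(work, params)
    relax(work, params, inplace=True, _system=sys)
    initial = tissue_areas(work)
    total0 = work.total_area()
    if target_extension is not None:
        if target_extension < 1.0:
            raise ValueError("target extension must be >= 1")
        target_area = target_extension * total0
    if target_area is not None and target_area < total0:
        raise ValueError("target area is below the relaxed initial area")
    trajectory = [total0]
    steps = 0
    while True:
        if step_budget is not None:
            if steps >= step_budget:
                break
        elif trajectory[-1] >= target_area:
            break
        if steps >= params.max_growth_steps:
            raise SimulationError("growth-step cap reached before the area target")
        grow_step(work, params, inplace=True, _system=sys)
        steps += 1
        total = work.total_area()
        if target_area is not None and total - trajectory[-1] < 1e-9:
            raise SimulationError(
                f"growth stalled at area {total:.6g} before target {target_area:.6g}"
            )
        trajectory.append(total)
    final = tissue_areas(work)
    in0, out0 = _group_areas(initial)
    in1, out1 = _group_areas(final)
    return SimResult(
        tissue_initial=initial,
        tissue_final=final,
        inner_extension=in1 / in0 if in0 > 0 else float("nan"),
        outer_extension=out1 / out0 if out0 > 0 else float("nan"),
        steps=steps,
        area_trajectory=np.array(trajectory),
        final_mesh=work,
    )


# ---------------------------------------------------------------------------
# Stiffness-multiplier fitting
# ---------------------------------------------------------------------------

@dataclass
class StiffnessFitResult:
    """Inner/outer stiffness multipliers matching target area extensions."""

    inner_multiplier: float
    outer_multiplier: float
    step_budget: int
    residual: float  # max relative inner/outer extension error
    n_evaluations: int
    converged: bool
    history: list = field(default_factory=list)


class FitFailureError(RuntimeError):
    """Optimizer stagnated far from the targets; carries the sampled
    (inner, outer, residual) landscape for inspection."""

    def __init__(self, message: str, history):
        super().__init__(message)
        self.history = history


class _Converged(Exception):
    def __init__(self, x, residual):
        self.x = x
        self.residual = residual


def fit_stiffness_multipliers(
    mesh: CrossSectionMesh,
    params_wt: SimParams,
    target_inner: float,
    target_outer: float,
    wt_steps: int,
    relative_time: float = 1.0,
    start: Tuple[float, float] = (1.0, 1.0),
    residual_tol: float = 1e-3,
    max_evaluations: int = 200,
    inner_classes=INNER_WALL_CLASSES,
) -> StiffnessFitResult:
    """Fit group stiffness multipliers to inner/outer extension targets.

    The growth-step budget is ``round(relative_time × wt_steps)`` — the
    genotype's residence time in the meristem relative to the WT sets how
    long its section grows. Nelder–Mead searches (log inner, log outer)
    multiplier space from ``start``, minimizing the maximum relative
    error of the simulated inner and outer group extensions against the
    targets; the search stops as converged once the residual drops below
    ``residual_tol`` (0.001 = the 0.1% match quality achievable for
    simulator-generated targets). If the optimizer exhausts its budget
    with residual above 5%, a :class:`FitFailureError` carrying the
    sampled landscape is raised.
    """
    if target_inner <= 0 or target_outer <= 0:
        raise ValueError("targets must be positive extensions")
    budget = max(1, int(round(relative_time * wt_steps)))
    history: list = []

    def objective(logm: np.ndarray) -> float:
        m_in, m_out = float(np.exp(logm[0])), float(np.exp(logm[1]))
        params = params_wt.scaled_stiffness(m_in, m_out, inner_classes)
        res = simulate_to_area(mesh, params, step_budget=budget)
        residual = max(
            abs(res.inner_extension / target_inner - 1.0),
            abs(res.outer_extension / target_outer - 1.0),
        )
        history.append((m_in, m_out, residual))
        if residual < residual_tol:
            raise _Converged(logm, residual)
        return residual

    x0 = np.log(np.asarray(start, dtype=float))
    try:
        nm = optimize.minimize(
            objective,
            x0,
            method="Nelder-Mead",
            options={
                "maxfev": max_evaluations,
                "xatol": 1e-4,
                "fatol": residual_tol / 10,
                "initial_simplex": np.array(
                    [x0, x0 + [0.25, 0.0], x0 + [0.0, 0.25]]
                ),
            },
        )
        best = min(history, key=lambda h: h[2])
        m_in, m_out, residual = best
        converged = residual < residual_tol
    except _Converged as c:
        m_in, m_out = np.exp(c.x)
        residual = c.residual
        converged = True
    if not converged and residual > 0.05:
        raise FitFailureError(
            f"stiffness fit stagnated at residual {residual:.3g}", history
        )
    return StiffnessFitResult(
        inner_multiplier=float(m_in),
        outer_multiplier=float(m_out),
        step_budget=budget,
        residual=float(residual),
        n_evaluations=len(history),
        converged=converged,
        history=history,
    )
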