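"""Agent-based substrate: soft-sphere cell mechanics, division, growth.

Cells are overdamped soft spheres in 3D (optionally a 2D layer).  Pairs
closer than the sum of their radii repel with a linear spring; pairs within
``interaction_cutoff`` times the contact distance adhere weakly; a weak
spring toward the live-cell centroid keeps the aggregate compact (the model
covers the ICM only — no trophectoderm or cavity geometry).  Cells divide
when their cycle clock expires; division times are jittered around the mean
cycle so the population desynchronizes, and daughters inherit the mother's
NANOG level up to a small multiplicative perturbation.

The fate circuit (:mod:`icmfate.circuit`) is switched on once the aggregate
reaches a configurable size and is then integrated in lock-step with the
mechanics on the current signaling neighbor graph.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Callable, Optional

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .circuit import CircuitParams, StepSizeError, mean_field, nanog_rhs, find_equilibria

__all__ = [
    "MechanicsParams",
    "GrowthConfig",
    "CellAgent",
    "EmbryoState",
    "pairwise_force",
    "step_positions",
    "neighbor_graph",
    "divide_cell",
    "grow_embryo",
    "equilibrium_levels",
    "seeded_rng",
]

STATUS_DP = "DP"
STATUS_EPI = "EPI"
STATUS_PRE = "PrE"
STATUS_ESC = "ESC"


def seeded_rng(seed: int, *labels: str) -> np.random.Generator:
    """Deterministic per-component random stream.

    A master seed is combined with stable CRC32 hashes of string labels, so
    each component of a run draws from an independent stream.
    """
    entropy = [int(seed)] + [zlib.crc32(lab.encode()) for lab in labels]
    return np.random.default_rng(np.random.SeedSequence(entropy))


@dataclass(frozen=True)
class MechanicsParams:
    """Soft-sphere and cell-cycle constants (lengths in cell radii, time in hours)."""

    repulsion_stiffness: float = 5.0   # force per unit overlap
    adhesion_strength: float = 0.5     # peak attractive force in the adhesion shell
    interaction_cutoff: float = 1.5    # shell outer edge, in multiples of contact distance
    drag: float = 1.0                  # force * time / length
    mean_cycle: float = 10.0           # hours between divisions
    cycle_jitter: float = 0.3          # uniform fractional jitter of the cycle
    confinement_stiffness: float = 0.3  # centroid spring
    division_offset: float = 0.25      # daughter displacement from mother center
    inheritance_sd: float = 0.05       # sd of log-normal x jitter at division

    def __post_init__(self) -> None:
        for name in ("repulsion_stiffness", "adhesion_strength", "interaction_cutoff",
                     "drag", "mean_cycle", "division_offset"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 <= self.cycle_jitter < 1:
            raise ValueError("cycle_jitter must be in [0, 1)")


@dataclass(frozen=True)
class GrowthConfig:
    """Parameters of a growth run (the wild-type in-silico experiment)."""

    target_size: int = 27          # live host ICM cells at which growth stops
    n_initial: int = 2             # founder cells
    grn_on_size: int = 8           # live-cell count at which the circuit activates
    dt: float = 0.01               # shared mechanics/circuit step, hours
    relax_hours: float = 6.0       # post-target integration with divisions off
    end_time: Optional[float] = None  # absolute end of the run (hours); None = target + relax
    coupling_cutoff: float | str = 1.5  # signaling range; "global" couples all cells
    dimensionality: int = 3
    init_x_sd: float = 0.1         # log-sd of initial NANOG around the DP level
    circuit: CircuitParams = field(default_factory=CircuitParams)
    mechanics: MechanicsParams = field(default_factory=MechanicsParams)

    def __post_init__(self) -> None:
        if self.target_size < self.n_initial:
            raise ValueError("target_size must be >= n_initial")
        if self.n_initial < 1:
            raise ValueError("need at least one founder cell")
        if self.dimensionality not in (2, 3):
            raise ValueError("dimensionality must be 2 or 3")


@dataclass
class CellAgent:
    """One ICM cell (positions in cell-radius units, times in hours)."""

    id: int
    position: np.ndarray
    radius: float = 1.0
    x: float = 0.0
    status: str = STATUS_DP
    birth_time: float = 0.0
    next_division: float = np.inf
    alive: bool = True


class EmbryoState:
    """Array-backed collection of cell agents at a simulation time.

    Internally stores flat numpy arrays for speed; :attr:`cells` materializes
    :class:`CellAgent` views for inspection.  Dead cells stay in the arrays
    (masked out) so ids remain stable.
    """

    def __init__(self, ids, positions, radii, x, status, birth, next_division,
                 alive, t: float = 0.0, dimensionality: int = 3):
        self.ids = np.asarray(ids, dtype=int)
        if len(np.unique(self.ids)) != len(self.ids):
            raise ValueError("cell ids must be unique")
        self.positions = np.asarray(positions, dtype=float).reshape(len(self.ids), 3)
        self.radii = np.asarray(radii, dtype=float)
        self.x = np.asarray(x, dtype=float)
        self.status = np.asarray(status, dtype=object)
        self.birth = np.asarray(birth, dtype=float)
        self.next_division = np.asarray(next_division, dtype=float)
        self.alive = np.asarray(alive, dtype=bool)
        self.t = float(t)
        self.dimensionality = int(dimensionality)

    @classmethod
    def from_cells(cls, cells: list[CellAgent], t: float = 0.0,
                   dimensionality: int = 3) -> "EmbryoState":
        return cls(
            ids=[c.id for c in cells],
            positions=[np.asarray(c.position, dtype=float) for c in cells],
            radii=[c.radius for c in cells],
            x=[c.x for c in cells],
            status=[c.status for c in cells],
            birth=[c.birth_time for c in cells],
            next_division=[c.next_division for c in cells],
            alive=[c.alive for c in cells],
            t=t, dimensionality=dimensionality,
        )

    @property
    def cells(self) -> list[CellAgent]:
        return [CellAgent(id=int(self.ids[i]), position=self.positions[i].copy(),
                          radius=float(self.radii[i]), x=float(self.x[i]),
                          status=str(self.status[i]), birth_time=float(self.birth[i]),
                          next_division=float(self.next_division[i]),
                          alive=bool(self.alive[i]))
                for i in range(len(self.ids))]

    @property
    def n_live(self) -> int:
        return int(self.alive.sum())

    @property
    def n_live_host(self) -> int:
        return int((self.alive & (self.status != STATUS_ESC)).sum())

    def copy(self) -> "EmbryoState":
        return EmbryoState(self.ids.copy(), self.positions.copy(), self.radii.copy(),
                           self.x.copy(), self.status.copy(), self.birth.copy(),
                           self.next_division.copy(), self.alive.copy(),
                           t=self.t, dimensionality=self.dimensionality)


def pairwise_force(distance: float, r1: float, r2: float,
                   mp: MechanicsParams = MechanicsParams()) -> float:
    """Signed center-line force between two cells (positive = repulsive).

    Linear spring repulsion inside contact; a tent-shaped weak attraction in
    the adhesion shell (zero at contact and at the outer cutoff, so the law
    is continuous everywhere).
    """
    if distance <= 0:
        raise ValueError("coincident cell centers")
    contact = r1 + r2
    outer = mp.interaction_cutoff * contact
    if distance >= outer:
        return 0.0
    if distance < contact:
        return mp.repulsion_stiffness * (contact - distance)
    half = (outer - contact) / 2.0
    if half == 0:
        return 0.0
    return -mp.adhesion_strength * (half - abs(distance - (contact + half))) / half


def _pair_geometry(pos: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Center-to-center difference vectors and distances (dense, small N)."""
    diff = pos[:, None, :] - pos[None, :, :]
    dist = np.sqrt(np.einsum("ijk,ijk->ij", diff, diff))
    return diff, dist


def _net_forces(pos: np.ndarray, radii: np.ndarray, mp: MechanicsParams,
                dist: Optional[np.ndarray] = None,
                diff: Optional[np.ndarray] = None) -> np.ndarray:
    """Vectorized soft-sphere + centroid-confinement forces for live cells."""
    n = len(pos)
    F = np.zeros_like(pos)
    if n > 1:
        if dist is None or diff is None:
            diff, dist = _pair_geometry(pos)
        contact = radii[:, None] + radii[None, :]
        outer = mp.interaction_cutoff * contact
        d = np.where(dist > 0, dist, 1.0)
        mag = np.zeros_like(dist)
        overlap = dist < contact
        mag[overlap] = (mp.repulsion_stiffness * (contact - dist))[overlap]
        shell = (dist >= contact) & (dist < outer)
        half = (outer - contact) / 2.0
        tent = mp.adhesion_strength * (half - np.abs(dist - (contact + half))) / np.where(half > 0, half, 1.0)
        mag[shell] = -tent[shell]
        np.fill_diagonal(mag, 0.0)
        F = np.einsum("ij,ijk->ik", mag / d, diff)
    centroid = pos.mean(axis=0)
    F -= mp.confinement_stiffness * (pos - centroid)
    return F


def step_positions(e: EmbryoState, mp: MechanicsParams = MechanicsParams(),
                   dt: float = 0.01) -> EmbryoState:
    """One overdamped position update; returns a new state.

    Raises :class:`~icmfate.circuit.StepSizeError` if any displacement
    exceeds a tenth of the smallest radius.
    """
    out = e.copy()
    _step_positions_inplace(out, mp, dt)
    out.t = e.t + dt
    return out


def _step_positions_inplace(e: EmbryoState, mp: MechanicsParams, dt: float,
                            dist: Optional[np.ndarray] = None,
                            diff: Optional[np.ndarray] = None) -> None:
    live = e.alive
    if not live.any():
        return
    pos = e.positions[live]
    F = _net_forces(pos, e.radii[live], mp, dist=dist, diff=diff)
    disp = F / mp.drag * dt
    if e.dimensionality == 2:
        disp[:, 2] = 0.0
    cap = 0.1 * e.radii[live].min()
    maxdisp = np.linalg.norm(disp, axis=1).max()
    if maxdisp > cap:
        raise StepSizeError(f"max displacement {maxdisp:.3f} exceeds {cap:.3f}; reduce dt")
    e.positions[live] = pos + disp


def neighbor_graph(e: EmbryoState, cutoff: float | str = 1.5
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Signaling adjacency over live cells, always with self-loops.

    Returns ``(live_indices, adjacency)``.  ``cutoff="global"`` gives the
    complete graph (the widely-diffusing-ligand limit); otherwise cells are
    coupled iff their center distance is at most ``cutoff * (r_i + r_j)``.
    """
    live_idx = np.flatnonzero(e.alive)
    n = len(live_idx)
    if cutoff == "global":
        return live_idx, np.ones((n, n), dtype=bool)
    if not (isinstance(cutoff, (int, float)) and cutoff > 0):
        raise ValueError("cutoff must be positive or 'global'")
    pos = e.positions[live_idx]
    radii = e.radii[live_idx]
    dist = squareform(pdist(pos)) if n > 1 else np.zeros((1, 1))
    A = dist <= cutoff * (radii[:, None] + radii[None, :])
    np.fill_diagonal(A, True)
    return live_idx, A


def _random_direction(rng: np.random.Generator, dim: int) -> np.ndarray:
    v = rng.normal(size=3)
    if dim == 2:
        v[2] = 0.0
    nrm = np.linalg.norm(v)
    return v / nrm if nrm > 0 else np.array([1.0, 0.0, 0.0])


def divide_cell(c: CellAgent, t: float, rng: np.random.Generator,
                mp: MechanicsParams = MechanicsParams(), id_start: int = 0,
                dim: int = 3, x_max: float = np.inf) -> tuple[CellAgent, CellAgent]:
    """Split one cell into two daughters displaced along a random axis.

    Each daughter redraws its cycle clock with uniform jitter and inherits
    the mother's NANOG level with a small log-normal perturbation — unless
    the mother is an ESC, whose level is lineage-restricted and stays frozen.
    """
    if not c.alive:
        raise ValueError("cannot divide a dead cell")
    if t < c.next_division:
        raise ValueError("cell is not due to divide")
    axis = _random_direction(rng, dim)
    daughters = []
    for k, sign in enumerate((+1.0, -1.0)):
        if c.status == STATUS_ESC:
            x_d = c.x
        else:
            x_d = float(np.clip(c.x * np.exp(rng.normal(0.0, mp.inheritance_sd)),
                                0.0, x_max))
        cycle = mp.mean_cycle * (1.0 + rng.uniform(-mp.cycle_jitter, mp.cycle_jitter))
        daughters.append(CellAgent(
            id=id_start + k,
            position=np.asarray(c.position, dtype=float) + sign * mp.division_offset * axis,
            radius=c.radius, x=x_d, status=c.status, birth_time=t,
            next_division=t + cycle, alive=True))
    return daughters[0], daughters[1]


def default_end_time(cfg: GrowthConfig) -> float:
    """Nominal developmental end point of a run (hours).

    The expected time for the founders to produce the target count at the
    mean cycle (plus half a cycle of start-up lag), plus the post-target
    relaxation window.  Staged-perturbation experiments fix this as an
    absolute end time so that later perturbations genuinely leave less
    recovery time, as a fixed implantation deadline does in vivo.
    """
    doublings = np.log2(cfg.target_size / cfg.n_initial)
    return cfg.mechanics.mean_cycle * (doublings + 0.5) + cfg.relax_hours


def equilibrium_levels(p: CircuitParams) -> tuple[float, float, float]:
    """(low, saddle, high) NANOG levels of the default two-cluster portrait."""
    return _equilibrium_levels_cached(p)


_EQ_CACHE: dict[CircuitParams, tuple[float, float, float]] = {}


def _equilibrium_levels_cached(p: CircuitParams) -> tuple[float, float, float]:
    if p not in _EQ_CACHE:
        eqs = find_equilibria(p)
        stable_off = [e for e in eqs if e.is_stable and not e.on_diagonal]
        diag = [e for e in eqs if e.on_diagonal]
        if not stable_off or not diag:
            raise ValueError("circuit parameters are not in the bistable regime")
        hi = max(max(e.point) for e in stable_off)
        lo = min(min(e.point) for e in stable_off)
        _EQ_CACHE[p] = (lo, float(np.mean(diag[0].point)), hi)
    return _EQ_CACHE[p]


def grow_embryo(config: GrowthConfig = GrowthConfig(), seed: int = 0, *,
                n_esc_at_activation: int = 0,
                interventions: Optional[dict[int, Callable]] = None,
                observer: Optional[Callable[[EmbryoState], None]] = None,
                observe_every: float = 1.0) -> EmbryoState:
    """Grow an ICM from founders to the target size with the circuit running.

    The loop interleaves overdamped mechanics, jittered division events and
    explicit-Euler integration of the fate circuit on the current neighbor
    graph.  The circuit switches on the first time the live host count
    reaches ``config.grn_on_size``; at that moment ``n_esc_at_activation``
    ESC agents (frozen at the high-NANOG equilibrium) may be aggregated onto
    the embryo.  ``interventions`` maps live-host-cell counts to callables
    ``f(embryo, rng)`` fired once when that size is first reached (used for
    staged ablations).  Fully reproducible given ``seed``.
    """
    cfg = config
    mp = cfg.mechanics
    rng = seeded_rng(seed, "embryo")
    dim = cfg.dimensionality
    x_lo, x_sad, x_hi = equilibrium_levels(cfg.circuit)

    # founders in a loose ball around the origin
    n0 = cfg.n_initial
    pos = rng.normal(scale=0.5, size=(n0, 3))
    if dim == 2:
        pos[:, 2] = 0.0
    cycles = mp.mean_cycle * (1.0 + rng.uniform(-mp.cycle_jitter, mp.cycle_jitter, n0))
    e = EmbryoState(
        ids=np.arange(n0), positions=pos, radii=np.ones(n0), x=np.zeros(n0),
        status=np.array([STATUS_DP] * n0, dtype=object), birth=np.zeros(n0),
        next_division=cycles, alive=np.ones(n0, dtype=bool),
        t=0.0, dimensionality=dim)

    next_id = n0
    grn_on = False
    pending = dict(interventions or {})
    fired: set[int] = set()
    relax_until: Optional[float] = None
    next_observe = 0.0

    def maybe_events():
        nonlocal next_id, grn_on, relax_until
        # division events due now (skipped once the target is reached)
        due = np.flatnonzero(e.alive & (e.next_division <= e.t))
        for i in due:
            if relax_until is not None:
                e.next_division[i] = np.inf
                continue
            mother = CellAgent(id=int(e.ids[i]), position=e.positions[i].copy(),
                               radius=float(e.radii[i]), x=float(e.x[i]),
                               status=str(e.status[i]), birth_time=float(e.birth[i]),
                               next_division=float(e.next_division[i]), alive=True)
            d1, d2 = divide_cell(mother, e.t, rng, mp, id_start=next_id, dim=dim,
                                 x_max=cfg.circuit.alpha)
            next_id += 2
            e.alive[i] = False  # mother replaced by two daughters
            _append(e, [d1, d2])
            after_size_change()

    def after_size_change():
        nonlocal grn_on, relax_until, next_id
        host = e.n_live_host
        if not grn_on and host >= cfg.grn_on_size:
            grn_on = True
            dp = e.alive & (e.status != STATUS_ESC)
            e.x[dp] = np.clip(x_sad * np.exp(rng.normal(0.0, cfg.init_x_sd, dp.sum())),
                              0.0, cfg.circuit.alpha)
            if n_esc_at_activation > 0:
                _append(e, _make_escs(n_esc_at_activation, e, rng, mp, x_hi, dim,
                                      id_start=next_id))
                next_id += n_esc_at_activation
        for size in sorted(pending):
            if size not in fired and host >= size:
                fired.add(size)
                pending[size](e, rng)
        if e.n_live_host >= cfg.target_size and relax_until is None:
            relax_until = e.t + cfg.relax_hours
            e.next_division[e.alive] = np.inf

    after_size_change()
    guard_hours = mp.mean_cycle * (4 + 2 * np.log2(max(cfg.target_size, 2)))
    while True:
        maybe_events()
        live = np.flatnonzero(e.alive)
        pos = e.positions[live]
        if len(live) > 1:
            diff, dist = _pair_geometry(pos)
        else:
            diff, dist = np.zeros((1, 1, 3)), np.zeros((1, 1))
        _step_positions_inplace(e, mp, cfg.dt, dist=dist, diff=diff)
        if grn_on:
            if cfg.coupling_cutoff == "global":
                A = np.ones((len(live), len(live)), dtype=bool)
            else:
                radii = e.radii[live]
                A = dist <= cfg.coupling_cutoff * (radii[:, None] + radii[None, :])
                np.fill_diagonal(A, True)
            xl = e.x[live]
            fld = mean_field(xl, A)
            upd = e.status[live] != STATUS_ESC
            xn = xl.copy()
            xn[upd] = xl[upd] + cfg.dt * nanog_rhs(xl[upd], fld[upd], cfg.circuit)
            if np.any(xn < 0) or np.any(xn > cfg.circuit.alpha * 1.05):
                raise StepSizeError("circuit state left [0, 1.05*alpha]; reduce dt")
            e.x[live] = xn
        e.t += cfg.dt
        if observer is not None and e.t >= next_observe:
            observer(e)
            next_observe += observe_every
        if cfg.end_time is not None:
            if e.t >= cfg.end_time:
                break
        elif relax_until is not None and e.t >= relax_until:
            break
        if e.t > guard_hours:
            raise RuntimeError("growth did not reach the target size in time")
    if observer is not None:
        observer(e)
    return e


def _make_escs(n: int, e: EmbryoState, rng: np.random.Generator,
               mp: MechanicsParams, x_hi: float, dim: int,
               id_start: int) -> list[CellAgent]:
    """ESC agents placed at the aggregate surface, frozen at high NANOG."""
    centroid = e.positions[e.alive].mean(axis=0)
    cells = []
    placed = [e.positions[i] for i in np.flatnonzero(e.alive)]
    for k in range(n):
        d = _random_direction(rng, dim)
        # clear every already-placed cell along the chosen direction
        reach = max(float(np.dot(p - centroid, d)) for p in placed)
        pos = centroid + d * (reach + 2.05)
        placed.append(pos)
        cycle = mp.mean_cycle * (1.0 + rng.uniform(-mp.cycle_jitter, mp.cycle_jitter))
        cells.append(CellAgent(id=id_start + k, position=pos,
                               radius=1.0, x=x_hi, status=STATUS_ESC,
                               birth_time=e.t, next_division=e.t + cycle, alive=True))
    return cells


def _append(e: EmbryoState, cells: list[CellAgent]) -> None:
    k = len(cells)
    e.ids = np.concatenate([e.ids, [c.id for c in cells]])
    e.positions = np.vstack([e.positions, [np.asarray(c.position, dtype=float) for c in cells]])
    e.radii = np.concatenate([e.radii, [c.radius for c in cells]])
    e.x = np.concatenate([e.x, [c.x for c in cells]])
    e.status = np.concatenate([e.status, np.array([c.status for c in cells], dtype=object)])
    e.birth = np.concatenate([e.birth, [c.birth_time for c in cells]])
    e.next_division = np.concatenate([e.next_division, [c.next_division for c in cells]])
    e.alive = np.concatenate([e.alive, [c.alive for c in cells]])
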