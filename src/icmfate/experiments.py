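"""In-silico experiment suite: wild type, scaling, ESC chimeras, ablation.

Continuous NANOG levels are mapped to the three ICM classes (epiblast, DP
progenitor, PrE) by thresholds that bracket the unstable symmetric state of
the two-cluster portrait, so a committed cell sits in the basin whose label
it carries.  ESC agents are lineage-restricted epiblast equivalents: they
are counted in the epiblast compartment of the total composition but never
re-enter the decision circuit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .circuit import CircuitParams
from .mechanics import (EmbryoState, GrowthConfig, STATUS_DP, STATUS_EPI,
                        STATUS_ESC, STATUS_PRE, default_end_time,
                        equilibrium_levels, grow_embryo, seeded_rng)

__all__ = [
    "IdentityThresholds",
    "CompositionSummary",
    "RunResult",
    "default_thresholds",
    "assign_identity",
    "identities",
    "composition",
    "run_wildtype",
    "run_scaling",
    "run_chimera",
    "ablate",
    "run_ablation_series",
    "run_batch",
    "sensitivity_sweep",
]


@dataclass(frozen=True)
class IdentityThresholds:
    """NANOG levels separating the three ICM classes (lo < hi).

    ``x > hi`` reads out epiblast, ``x < lo`` PrE, anything between is an
    uncommitted DP progenitor.
    """

    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise ValueError("need lo < hi")


def default_thresholds(p: CircuitParams = CircuitParams()) -> IdentityThresholds:
    """Thresholds at the midpoints between the saddle and each stable level."""
    x_lo, x_sad, x_hi = equilibrium_levels(p)
    return IdentityThresholds(lo=(x_lo + x_sad) / 2.0, hi=(x_sad + x_hi) / 2.0)


def assign_identity(x, th: IdentityThresholds):
    """Map NANOG level(s) to 'EPI' / 'DP' / 'PrE'. Vectorized."""
    xv = np.asarray(x, dtype=float)
    if np.any(xv < 0):
        raise ValueError("x must be non-negative")
    out = np.full(xv.shape, STATUS_DP, dtype=object)
    out[xv > th.hi] = STATUS_EPI
    out[xv < th.lo] = STATUS_PRE
    return out if out.ndim else str(out)


def identities(e: EmbryoState, th: IdentityThresholds) -> np.ndarray:
    """Per-live-cell labels; ESCs keep their own label."""
    live = np.flatnonzero(e.alive)
    lab = assign_identity(e.x[live], th)
    lab[e.status[live] == STATUS_ESC] = STATUS_ESC
    return lab


@dataclass(frozen=True)
class CompositionSummary:
    """Lineage counts and fractions of one embryo's live ICM.

    Fractions are taken over all live ICM cells with ESCs folded into the
    epiblast compartment (their fate in chimeras); ``ln_ratio`` is
    ``ln(PrE : EPI)`` on the same convention and NaN when either count is 0.
    Host-only fractions exclude the ESC compartment entirely.
    """

    n_epi: int
    n_pre: int
    n_dp: int
    n_esc: int = 0
    t: float = float("nan")

    @property
    def n_total(self) -> int:
        return self.n_epi + self.n_pre + self.n_dp + self.n_esc

    @property
    def frac_epi(self) -> float:
        return (self.n_epi + self.n_esc) / self.n_total if self.n_total else math.nan

    @property
    def frac_pre(self) -> float:
        return self.n_pre / self.n_total if self.n_total else math.nan

    @property
    def frac_dp(self) -> float:
        return self.n_dp / self.n_total if self.n_total else math.nan

    @property
    def ln_ratio(self) -> float:
        epi = self.n_epi + self.n_esc
        if self.n_pre > 0 and epi > 0:
            return math.log(self.n_pre / epi)
        return math.nan

    @property
    def host_frac_epi(self) -> float:
        host = self.n_epi + self.n_pre + self.n_dp
        return self.n_epi / host if host else math.nan

    def as_dict(self) -> dict:
        return {"t": self.t, "n_epi": self.n_epi, "n_pre": self.n_pre,
                "n_dp": self.n_dp, "n_esc": self.n_esc, "n_total": self.n_total,
                "frac_epi": self.frac_epi, "frac_pre": self.frac_pre,
                "frac_dp": self.frac_dp, "ln_ratio": self.ln_ratio,
                "host_frac_epi": self.host_frac_epi}


def composition(e: EmbryoState, th: Optional[IdentityThresholds] = None,
                p: Optional[CircuitParams] = None) -> CompositionSummary:
    """Classify all live cells and tally the lineage composition."""
    if th is None:
        th = default_thresholds(p or CircuitParams())
    lab = identities(e, th)
    return CompositionSummary(
        n_epi=int(np.sum(lab == STATUS_EPI)),
        n_pre=int(np.sum(lab == STATUS_PRE)),
        n_dp=int(np.sum(lab == STATUS_DP)),
        n_esc=int(np.sum(lab == STATUS_ESC)),
        t=e.t)


@dataclass
class RunResult:
    """Outcome of one simulated embryo."""

    final: EmbryoState
    summary: CompositionSummary
    trajectory: Optional[pd.DataFrame] = None
    n_divisions: int = 0
    n_esc_added: int = 0


def _make_observer(cfg: GrowthConfig, th: IdentityThresholds, rows: list) -> callable:
    def obs(e: EmbryoState) -> None:
        rows.append(composition(e, th).as_dict())
    return obs


def _run(cfg: GrowthConfig, seed: int, *, n_esc: int = 0,
         interventions: Optional[dict] = None, record: bool = True,
         record_every: float = 1.0) -> RunResult:
    th = default_thresholds(cfg.circuit)
    rows: list[dict] = []
    obs = _make_observer(cfg, th, rows) if record else None
    final = grow_embryo(cfg, seed, n_esc_at_activation=n_esc,
                        interventions=interventions, observer=obs,
                        observe_every=record_every)
    n_div = (len(final.ids) - cfg.n_initial - n_esc) // 2
    return RunResult(final=final, summary=composition(final, th),
                     trajectory=pd.DataFrame(rows) if record else None,
                     n_divisions=n_div, n_esc_added=n_esc)


def run_wildtype(config: GrowthConfig = GrowthConfig(), seed: int = 0, *,
                 record: bool = True, record_every: float = 1.0) -> RunResult:
    """One wild-type growth run to the target ICM size."""
    return _run(config, seed, record=record, record_every=record_every)


def run_scaling(factor: float, config: GrowthConfig = GrowthConfig(),
                seed: int = 0, *, record: bool = False) -> RunResult:
    """Wild-type run with the target ICM size scaled by ``factor``."""
    target = int(round(config.target_size * factor))
    if target < 4:
        raise ValueError("scaled target must be at least 4 cells")
    cfg = replace(config, target_size=target,
                  grn_on_size=min(config.grn_on_size, max(target // 2, 2)))
    return _run(cfg, seed, record=record)


def run_chimera(n_esc: int, config: GrowthConfig = GrowthConfig(),
                seed: int = 0, *, record: bool = False) -> RunResult:
    """Aggregation chimera: ``n_esc`` ESCs joined just before circuit activation.

    ESCs secrete growth factor (they enter their neighbors' mean field at
    the frozen high-NANOG level) but never change state; they divide like
    host cells.
    """
    if n_esc < 0:
        raise ValueError("n_esc must be non-negative")
    return _run(config, seed, n_esc=n_esc, record=record)


_LINEAGES = (STATUS_EPI, STATUS_PRE, STATUS_DP, "all", "random")


def _round_half_away(v: float) -> int:
    return int(math.floor(v + 0.5)) if v >= 0 else -int(math.floor(-v + 0.5))


def ablate(e: EmbryoState, lineage: str, fraction: float,
           rng: np.random.Generator,
           th: Optional[IdentityThresholds] = None) -> EmbryoState:
    """Remove a fraction of one lineage (in place) and return the state.

    ``lineage='all'`` removes the fraction from each of the three classes;
    ``'random'`` removes the fraction of all live host cells ignoring
    identity.  Removal rounds half away from zero, with a minimum of one
    cell whenever the fraction is positive and the target class non-empty.
    Removed cells are marked dead and drop out of the neighbor graph and
    the mean field from the next step on.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    if lineage not in _LINEAGES:
        raise ValueError(f"lineage must be one of {_LINEAGES}")
    if th is None:
        th = default_thresholds()
    live = np.flatnonzero(e.alive & (e.status != STATUS_ESC))
    lab = assign_identity(e.x[live], th)
    groups = ([STATUS_EPI, STATUS_PRE, STATUS_DP] if lineage == "all"
              else [lineage])
    for g in groups:
        pool = live if g == "random" else live[lab == g]
        if pool.size == 0:
            if lineage != "all":
                raise ValueError(f"no live cells in lineage {g!r}")
            continue
        k = max(_round_half_away(fraction * pool.size), 1)
        k = min(k, pool.size)
        kill = rng.choice(pool, size=k, replace=False)
        e.alive[kill] = False
        e.next_division[kill] = np.inf
    return e


def run_ablation_series(lineage: str, fraction: float, at_icm_size: int,
                        config: GrowthConfig = GrowthConfig(),
                        seeds: Iterable[int] = range(100)) -> pd.DataFrame:
    """Staged ablation arm: remove cells when the ICM first reaches a size.

    Growth pauses implicitly at the trigger (the removal is instantaneous),
    then resumes to the target; one row of final composition per seed.
    """
    if at_icm_size > config.target_size:
        raise ValueError("trigger size must be reachable before the target")
    th = default_thresholds(config.circuit)
    if config.end_time is None:
        # staged arms share one developmental deadline, so later triggers
        # leave less recovery time (compare against a control arm run with
        # the same convention)
        config = replace(config, end_time=default_end_time(config))
    rows = []
    for seed in seeds:
        iv = {at_icm_size: lambda e, rng: ablate(e, lineage, fraction, rng, th)}
        res = _run(config, seed, interventions=iv, record=False)
        row = res.summary.as_dict()
        row.update(seed=seed, lineage=lineage, fraction=fraction,
                   at_icm_size=at_icm_size, n_divisions=res.n_divisions)
        rows.append(row)
    return pd.DataFrame(rows)


def run_batch(seeds: Iterable[int], config: GrowthConfig = GrowthConfig(), *,
              runner: str = "wildtype", **kwargs) -> pd.DataFrame:
    """Final compositions for a batch of seeds (one row per embryo)."""
    fns = {"wildtype": run_wildtype, "scaling": run_scaling, "chimera": run_chimera}
    fn = fns[runner]
    rows = []
    for seed in seeds:
        if runner == "wildtype":
            res = fn(config=config, seed=seed, record=False)
        else:
            res = fn(kwargs["factor"] if runner == "scaling" else kwargs["n_esc"],
                     config=config, seed=seed, record=False)
        row = res.summary.as_dict()
        row.update(seed=seed, n_divisions=res.n_divisions,
                   n_esc_added=res.n_esc_added)
        rows.append(row)
    return pd.DataFrame(rows)


def _with_param(cfg: GrowthConfig, name: str, value) -> GrowthConfig:
    """Replace a possibly-nested config field, e.g. 'circuit.alpha'."""
    if "." in name:
        head, rest = name.split(".", 1)
        sub = getattr(cfg, head)
        return replace(cfg, **{head: replace(sub, **{rest: value})})
    return replace(cfg, **{name: value})


def sensitivity_sweep(param_grid: dict[str, Sequence],
                      config: GrowthConfig = GrowthConfig(),
                      seeds: Iterable[int] = range(20)) -> pd.DataFrame:
    """Batch statistics of the final composition over a parameter grid.

    ``param_grid`` maps (possibly dotted) config field names to value lists;
    the full Cartesian product is run.  One summary row per grid cell with
    the batch mean and SD of the final lineage fractions.
    """
    import itertools

    names = list(param_grid)
    seeds = list(seeds)
    rows = []
    for values in itertools.product(*(param_grid[n] for n in names)):
        cfg = config
        for n, v in zip(names, values):
            cfg = _with_param(cfg, n, v)
        batch = run_batch(seeds, cfg)
        row = dict(zip(names, values))
        row.update(n_seeds=len(seeds),
                   mean_frac_epi=batch["frac_epi"].mean(),
                   sd_frac_epi=batch["frac_epi"].std(),
                   mean_frac_pre=batch["frac_pre"].mean(),
                   sd_frac_pre=batch["frac_pre"].std(),
                   mean_frac_dp=batch["frac_dp"].mean())
        rows.append(row)
    return pd.DataFrame(rows)
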