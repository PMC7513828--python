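"""Synthetic data products with known ground truth.

Two generators emulate the tabular outputs the classification pipeline
consumes: per-cell segmented-fluorescence tables (the shape produced by
nuclear segmentation of fixed, immunostained blastocysts) and per-cell
time-lapse GFP tracks from ablation movies.  Both are pure functions of
their configuration and seed.

The intensity model is log-normal with identity-specific locations per
channel, a shared per-micron Z-decay slope, and a per-litter scale factor,
so the Z-correction, per-litter rescaling and clustering steps all have
something real to undo.  The default composition is the late-blastocyst
40% epiblast : 60% PrE split; targeted cells in ablation movies die with a
memoryless (exponential) clock whose default half-life is 3.4 hours,
censored at the movie end.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .mechanics import seeded_rng

__all__ = [
    "ChannelModel",
    "EmbryoGenConfig",
    "TrackGenConfig",
    "synth_embryo_table",
    "synth_litter",
    "synth_timelapse",
]


@dataclass(frozen=True)
class ChannelModel:
    """Log-normal intensity locations (natural-log units) per identity."""

    nanog_mu: dict = field(default_factory=lambda: {"EPI": 7.0, "DP": 6.8, "PrE": 5.8})
    gata6_mu: dict = field(default_factory=lambda: {"EPI": 5.8, "DP": 6.8, "PrE": 7.0})
    gfp_mu: dict = field(default_factory=lambda: {"EPI": 5.5, "DP": 6.4, "PrE": 7.0})
    sigma: float = 0.25  # shared log-scale noise; class locations sit >= 2 sigma apart

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")


@dataclass(frozen=True)
class EmbryoGenConfig:
    """Shape of one synthetic segmented embryo table."""

    n_icm: int = 25
    composition: tuple[float, float, float] = (0.4, 0.6, 0.0)  # (EPI, PrE, DP)
    channels: ChannelModel = field(default_factory=ChannelModel)
    z_decay_slope: float = -0.01   # log-intensity per micron of depth
    stack_depth: float = 80.0      # microns
    n_embryos_per_litter: int = 5
    litter_scale_sd: float = 0.3   # log-sd of the shared litter intensity factor

    def __post_init__(self) -> None:
        if self.n_icm < 1:
            raise ValueError("n_icm must be positive")
        if abs(sum(self.composition) - 1.0) > 1e-9 or min(self.composition) < 0:
            raise ValueError("composition fractions must be non-negative and sum to 1")


_IDENTITIES = ("EPI", "PrE", "DP")


def synth_embryo_table(cfg: EmbryoGenConfig = EmbryoGenConfig(), seed: int = 0,
                       embryo_id: str = "E1", litter_id: str = "L1",
                       litter_log_scale: float = 0.0,
                       cell_id_start: int = 0,
                       rng: Optional[np.random.Generator] = None
                       ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """One embryo's cell table plus its ground-truth label table.

    Cells sit at uniform depths through the stack; each channel's
    log-intensity is its identity-specific location plus the litter scale
    offset, the Z-decay trend, and Gaussian noise.
    """
    if rng is None:
        rng = seeded_rng(seed, "embryo_table", embryo_id)
    ident = rng.choice(_IDENTITIES, size=cfg.n_icm, p=list(cfg.composition))
    z = rng.uniform(0.0, cfg.stack_depth, cfg.n_icm)
    ch = cfg.channels
    rows = {"cell_id": np.arange(cell_id_start, cell_id_start + cfg.n_icm),
            "embryo_id": embryo_id, "litter_id": litter_id, "z": z,
            "ti_flag": "ICM"}
    for name, mus in (("nanog", ch.nanog_mu), ("gata6", ch.gata6_mu),
                      ("gfp", ch.gfp_mu)):
        mu = np.array([mus[i] for i in ident])
        logv = (mu + litter_log_scale + cfg.z_decay_slope * z
                + rng.normal(0.0, ch.sigma, cfg.n_icm))
        rows[f"{name}_raw"] = np.exp(logv)
    table = pd.DataFrame(rows)
    truth = table[["cell_id", "embryo_id", "litter_id"]].copy()
    truth["true_identity"] = ident
    return table, truth


def synth_litter(cfg: EmbryoGenConfig = EmbryoGenConfig(), n_embryos: int = 5,
                 seed: int = 0, litter_id_start: int = 1
                 ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Concatenated cell tables for several litters of embryos.

    ``n_embryos`` are split into litters of ``cfg.n_embryos_per_litter``;
    each litter shares a log-normal intensity scale factor, which is what
    makes per-litter rescaling meaningful downstream.
    """
    if n_embryos < 1:
        raise ValueError("need at least one embryo")
    rng = seeded_rng(seed, "litter")
    tables, truths = [], []
    cell_id = 0
    litter_idx = litter_id_start
    for e in range(n_embryos):
        if e % cfg.n_embryos_per_litter == 0:
            litter_scale = rng.normal(0.0, cfg.litter_scale_sd)
            if e > 0:
                litter_idx += 1
        t, tr = synth_embryo_table(cfg, embryo_id=f"E{e + 1}",
                                   litter_id=f"L{litter_idx}",
                                   litter_log_scale=litter_scale,
                                   cell_id_start=cell_id, rng=rng)
        cell_id += cfg.n_icm
        tables.append(t)
        truths.append(tr)
    return pd.concat(tables, ignore_index=True), pd.concat(truths, ignore_index=True)


@dataclass(frozen=True)
class TrackGenConfig:
    """Shape of a synthetic post-ablation time-lapse track table."""

    frame_interval_min: float = 15.0
    duration_hr: float = 18.0          # movies are 16-20 h; censoring time
    death_half_life_hr: float = 3.4    # targeted-cell exponential clock
    epi_level: float = 0.2             # GFP plateau of epiblast cells
    pre_start: float = 0.5             # starting GFP of PrE / DP cells
    pre_level: float = 1.0             # PrE plateau
    drift_rate: float = 0.12           # per-hour relaxation toward the fate level
    noise_sd: float = 0.03             # per-frame additive noise

    def __post_init__(self) -> None:
        if self.frame_interval_min <= 0 or self.duration_hr <= 0:
            raise ValueError("interval and duration must be positive")
        if self.death_half_life_hr <= 0:
            raise ValueError("half-life must be positive")


def synth_timelapse(cfg: TrackGenConfig = TrackGenConfig(), n_cells: int = 50,
                    targeted_ids: Sequence[int] = (), seed: int = 0,
                    fates: Optional[Sequence[str]] = None
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tracked-movie table: GFP traces, death events, ground-truth fates.

    Intact cells follow fate-specific dynamics — epiblast cells sit on a low
    plateau, PrE cells drift up toward the high plateau, DP cells start in
    between and relax toward a randomly chosen fate.  Targeted cells draw an
    exponential death time (half-life ``cfg.death_half_life_hr``) and are
    censored at the movie end; the death frame carries a ``death`` event.
    """
    rng = seeded_rng(seed, "timelapse")
    targeted = set(int(i) for i in targeted_ids)
    if not targeted.issubset(range(n_cells)):
        raise ValueError("targeted_ids must be existing cell ids")
    hours = cfg.frame_interval_min / 60.0
    n_frames = int(round(cfg.duration_hr / hours)) + 1
    rate = math.log(2.0) / cfg.death_half_life_hr

    if fates is None:
        fates = rng.choice(["EPI", "PrE", "DP"], size=n_cells, p=[0.3, 0.4, 0.3])
    else:
        fates = list(fates)
        if len(fates) != n_cells:
            raise ValueError("fates must have one entry per cell")

    rows, truth_rows = [], []
    for cid in range(n_cells):
        fate = fates[cid]
        dp_target = rng.choice(["EPI", "PrE"]) if fate == "DP" else fate
        level = {"EPI": cfg.epi_level, "PrE": cfg.pre_level}[dp_target]
        g = cfg.epi_level if fate == "EPI" else cfg.pre_start
        death_frame = None
        if cid in targeted:
            t_death = rng.exponential(1.0 / rate)
            if t_death < cfg.duration_hr:
                # record the event on the nearest frame of the 15-min grid
                # (unbiased discretization of the continuous death time)
                death_frame = int(round(t_death / hours))
        last = death_frame if death_frame is not None else n_frames - 1
        for f in range(last + 1):
            event = "death" if f == death_frame else "none"
            rows.append((cid, f, max(g + rng.normal(0.0, cfg.noise_sd), 0.0), event))
            # first-order relaxation toward the fate plateau
            g += cfg.drift_rate * (level - g) * hours * (4.0 if fate != "DP" else 1.5) \
                + rng.normal(0.0, cfg.noise_sd * 0.5)
        truth_rows.append((cid, fate, dp_target, cid in targeted,
                           death_frame is not None,
                           death_frame * hours if death_frame is not None else math.nan))
    tracks = pd.DataFrame(rows, columns=["cell_id", "frame", "gfp", "event"])
    truth = pd.DataFrame(truth_rows, columns=["cell_id", "true_fate", "dp_target",
                                              "targeted", "died", "death_time_hr"])
    return tracks, truth
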