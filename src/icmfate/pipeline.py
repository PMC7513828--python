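"""Quantitative processing of segmented-fluorescence tables and GFP tracks.

The chain mirrors how confocal stacks of immunostained blastocysts are
turned into per-cell identities:

1. correct log-intensities for fluorescence decay along the imaging Z axis
   (per embryo and channel, optionally with empirical-Bayes shrinkage of the
   per-embryo slopes toward their litter mean);
2. harmonize alternate antibodies onto the reference scale with a fitted
   affine map;
3. rescale each channel against its per-litter maximum;
4. classify ICM cells by UPGMA hierarchical clustering on the rescaled
   (NANOG, GATA6) plane, after setting aside rare double-negative cells;
5. for time-lapse GFP tracks: moving-average smoothing, a rule-based
   progenitor classifier (identity permanence + a 2-hour persistence
   requirement), and Kaplan-Meier survival of targeted cells.

Tables are tidy pandas DataFrames; see :mod:`icmfate.io` for the schema.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from lifelines import KaplanMeierFitter
from lifelines.utils import median_survival_times

__all__ = [
    "CalibrationMap",
    "CHANNELS",
    "zdecay_correct",
    "fit_calibration",
    "harmonize_antibody",
    "rescale_by_litter",
    "classify_icm",
    "smooth_gfp",
    "classify_track",
    "classify_tracks",
    "SurvivalResult",
    "survival_curve",
    "epi_equivalents",
]

CHANNELS = ("nanog", "gata6", "gfp")

EPI, PRE, DP, NANOG_LO, DN = "EPI", "PrE", "DP", "NANOG-lo", "DN"


# ---------------------------------------------------------------------------
# Z-decay correction

def _fit_slope(z: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """OLS slope of y ~ z and its squared standard error."""
    n = len(z)
    zc = z - z.mean()
    szz = float(zc @ zc)
    if szz == 0:
        return 0.0, math.inf
    slope = float(zc @ (y - y.mean())) / szz
    resid = y - y.mean() - slope * zc
    dof = max(n - 2, 1)
    se2 = float(resid @ resid) / dof / szz
    return slope, se2


def zdecay_correct(table: pd.DataFrame, mode: str = "eb",
                   channels: Sequence[str] = CHANNELS,
                   min_cells: int = 5) -> pd.DataFrame:
    """Remove the Z-axis fluorescence decay trend from each channel.

    Intensities (columns ``<channel>_raw``) are log-transformed; a linear
    model log-intensity ~ z is fitted per embryo and channel and its slope
    component subtracted about the embryo's mean depth.  ``mode='eb'``
    shrinks each embryo's slope toward the litter mean slope with
    normal-normal precision weights (embryo precision = 1 / squared SE of
    its OLS slope; litter prior variance by method of moments), which
    stabilizes embryos with few cells.  ``mode='linear'`` uses the raw
    per-embryo slopes.

    Returns a copy with corrected intensities written back on the linear
    scale and corrected logs in ``<channel>_log`` columns.
    """
    if mode not in ("linear", "eb"):
        raise ValueError("mode must be 'linear' or 'eb'")
    out = table.copy()
    for ch in channels:
        col = f"{ch}_raw"
        if col not in out.columns:
            continue
        logcol = np.log(out[col].astype(float).clip(lower=1e-12))
        fits = {}  # embryo -> (slope, se2, litter)
        for (embryo, litter), sub in out.groupby(["embryo_id", "litter_id"], sort=False):
            if len(sub) < min_cells:
                raise ValueError(
                    f"embryo {embryo!r} has fewer than {min_cells} cells for {ch}")
            slope, se2 = _fit_slope(sub["z"].to_numpy(dtype=float),
                                    logcol.loc[sub.index].to_numpy())
            fits[embryo] = [slope, se2, litter]
        if mode == "eb":
            by_litter: dict = {}
            for emb, (sl, se2, lit) in fits.items():
                by_litter.setdefault(lit, []).append((emb, sl, se2))
            for lit, items in by_litter.items():
                slopes = np.array([sl for _, sl, _ in items])
                se2s = np.array([s for _, _, s in items])
                mu = slopes.mean()
                # method-of-moments between-embryo variance, floored at 0
                tau2 = max(slopes.var(ddof=1) - se2s.mean(), 0.0) if len(items) > 1 else 0.0
                for (emb, sl, se2) in items:
                    if tau2 == 0.0:
                        shrunk = mu
                    else:
                        w = (1.0 / se2) / (1.0 / se2 + 1.0 / tau2)
                        shrunk = w * sl + (1.0 - w) * mu
                    fits[emb][0] = shrunk
        corrected = logcol.copy()
        for embryo, sub in out.groupby("embryo_id", sort=False):
            slope = fits[embryo][0]
            z = sub["z"].astype(float)
            corrected.loc[sub.index] = (logcol.loc[sub.index]
                                        - slope * (z - z.mean()))
        out[f"{ch}_log"] = corrected
        out[col] = np.exp(corrected)
    return out


# ---------------------------------------------------------------------------
# Antibody harmonization

@dataclass(frozen=True)
class CalibrationMap:
    """Affine map from an alternate antibody scale to the reference scale."""

    slope: float
    intercept: float = 0.0

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("slope must be positive")

    def apply(self, values):
        return self.slope * np.asarray(values, dtype=float) + self.intercept

    def invert(self, values):
        return (np.asarray(values, dtype=float) - self.intercept) / self.slope


def fit_calibration(alternate, reference) -> CalibrationMap:
    """Least-squares affine fit from double-stained paired measurements."""
    slope, intercept = np.polyfit(np.asarray(alternate, dtype=float),
                                  np.asarray(reference, dtype=float), 1)
    return CalibrationMap(slope=float(slope), intercept=float(intercept))


def harmonize_antibody(table: pd.DataFrame, calib: CalibrationMap,
                       channel: str = "nanog") -> pd.DataFrame:
    """Transform one channel onto the reference antibody scale."""
    out = table.copy()
    out[f"{channel}_raw"] = calib.apply(out[f"{channel}_raw"])
    return out


# ---------------------------------------------------------------------------
# Per-litter rescaling and UPGMA classification

def rescale_by_litter(table: pd.DataFrame,
                      channels: Sequence[str] = ("nanog", "gata6")) -> pd.DataFrame:
    """Divide each channel by its per-litter maximum (new ``<ch>`` columns in [0, 1])."""
    if "litter_id" not in table.columns:
        raise ValueError("litter_id column required")
    out = table.copy()
    for ch in channels:
        col = f"{ch}_raw"
        if col not in out.columns:
            continue
        out[ch] = out[col] / out.groupby("litter_id")[col].transform("max")
    return out


# archetype positions of the four ICM classes on the rescaled (NANOG, GATA6)
# plane; clusters are labeled by their nearest archetype, so several
# sub-clusters may share a label
_ARCHETYPES = {
    EPI: (0.55, 0.12),
    PRE: (0.12, 0.55),
    DP: (0.50, 0.50),
    NANOG_LO: (0.18, 0.08),
}


def classify_icm(table: pd.DataFrame, k_clusters: int = 4,
                 dn_threshold: float = 0.1) -> pd.DataFrame:
    """Assign ICM identities by UPGMA clustering on rescaled (NANOG, GATA6).

    Double-negative cells (both rescaled channels below ``dn_threshold``)
    are set aside before clustering — they are rare and usually mitotic or
    dying.  The remaining cells are clustered with average linkage (UPGMA)
    on Euclidean distance and the tree is cut at ``k_clusters``; each
    cluster takes the identity of the nearest class archetype (high NANOG /
    low GATA6 epiblast, the converse PrE, both high DP, both low with NANOG
    dominant NANOG-lo).  Row order does not affect the result.
    """
    for col in ("nanog", "gata6"):
        if col not in table.columns:
            raise ValueError("run rescale_by_litter first (nanog/gata6 columns missing)")
    out = table.copy()
    icm = out.index if "ti_flag" not in out.columns else out.index[out["ti_flag"] == "ICM"]
    X = out.loc[icm, ["nanog", "gata6"]].to_numpy(dtype=float)
    out.loc[:, "identity"] = "unassigned"
    dn = (X[:, 0] < dn_threshold) & (X[:, 1] < dn_threshold)
    out.loc[icm[dn], "identity"] = DN
    keep = icm[~dn]
    Xk = X[~dn]
    if k_clusters > len(keep):
        raise ValueError("more clusters requested than ICM cells")
    if len(keep) == 0:
        return out
    # stable order: sort by cell_id so linkage tie-breaking is reproducible
    order = np.argsort(out.loc[keep, "cell_id"].to_numpy(), kind="stable")
    Z = linkage(Xk[order], method="average", metric="euclidean")
    labels = fcluster(Z, t=k_clusters, criterion="maxclust")
    arch_names = list(_ARCHETYPES)
    arch = np.array([_ARCHETYPES[a] for a in arch_names])
    assigned = np.empty(len(keep), dtype=object)
    for c in np.unique(labels):
        centroid = Xk[order][labels == c].mean(axis=0)
        nearest = np.argmin(((arch - centroid) ** 2).sum(axis=1))
        assigned[labels == c] = arch_names[nearest]
    out.loc[keep[order], "identity"] = assigned
    return out


# ---------------------------------------------------------------------------
# Time-lapse GFP tracks

def smooth_gfp(track: pd.DataFrame, window: int = 4,
               value_col: str = "gfp") -> pd.DataFrame:
    """Centered moving average per cell (window shrinks at track edges)."""
    if window < 1:
        raise ValueError("window must be >= 1")
    out = track.sort_values(["cell_id", "frame"]).copy()
    out["smoothed_gfp"] = (out.groupby("cell_id")[value_col]
                           .transform(lambda s: s.rolling(window, center=True,
                                                          min_periods=1).mean()))
    return out


def _first_qualifying_run(qual: np.ndarray, run_len: int) -> Optional[int]:
    """Start index of the earliest run of >= run_len consecutive True."""
    count = 0
    for i, q in enumerate(qual):
        count = count + 1 if q else 0
        if count == run_len:
            return i - run_len + 1
    return None


def classify_track(track: pd.DataFrame,
                   pre_threshold: tuple[float, float],
                   epi_threshold: tuple[float, float],
                   persistence_hr: float = 2.0,
                   frame_interval_min: float = 15.0) -> pd.DataFrame:
    """Frame-by-frame identity of one tracked ICM cell from its GFP level.

    Thresholds are given at movie start and end and interpolated linearly
    across frames (the per-litter "threshold slope").  Two rules apply:
    a cell classified PrE or epiblast keeps that identity for the remainder
    of the movie, and a DP cell switches only once its smoothed GFP stays
    above the PrE threshold (or below the epiblast threshold) for at least
    ``persistence_hr`` — by default 8 consecutive 15-min frames.  The switch
    is stamped from the first frame of the qualifying run.  If both fates
    qualify starting at the same frame the cell is marked ``flagged``.
    """
    run_len = int(round(persistence_hr * 60.0 / frame_interval_min))
    t = track.sort_values("frame").copy()
    g = t["smoothed_gfp" if "smoothed_gfp" in t.columns else "gfp"].to_numpy(dtype=float)
    nf = len(t)
    frac = np.linspace(0.0, 1.0, nf) if nf > 1 else np.zeros(1)
    th_pre = pre_threshold[0] + frac * (pre_threshold[1] - pre_threshold[0])
    th_epi = epi_threshold[0] + frac * (epi_threshold[1] - epi_threshold[0])

    ident = np.full(nf, DP, dtype=object)
    flagged = False
    # identity at the first frame
    if g[0] > th_pre[0]:
        ident[:] = PRE
    elif g[0] < th_epi[0]:
        ident[:] = EPI
    else:
        s_pre = _first_qualifying_run(g > th_pre, run_len)
        s_epi = _first_qualifying_run(g < th_epi, run_len)
        if s_pre is not None and s_epi is not None and s_pre == s_epi:
            flagged = True
        elif s_pre is not None and (s_epi is None or s_pre <= s_epi):
            ident[s_pre:] = PRE
        elif s_epi is not None:
            ident[s_epi:] = EPI
    t["identity_at_frame"] = ident
    t["flagged"] = flagged
    return t


def classify_tracks(tracks: pd.DataFrame, pre_threshold, epi_threshold,
                    persistence_hr: float = 2.0,
                    frame_interval_min: float = 15.0) -> pd.DataFrame:
    """Apply :func:`classify_track` to every cell of a track table."""
    parts = [classify_track(sub, pre_threshold, epi_threshold,
                            persistence_hr, frame_interval_min)
             for _, sub in tracks.groupby("cell_id", sort=True)]
    return pd.concat(parts, ignore_index=True)


# ---------------------------------------------------------------------------
# Survival analysis

@dataclass
class SurvivalResult:
    """Product-limit survival estimate for one group of tracked cells."""

    times: np.ndarray
    survival: np.ndarray
    half_life: float            # first time S(t) <= 0.5; NaN if never reached
    half_life_ci: tuple[float, float]
    n: int
    n_events: int


def _tracks_to_durations(tracks: pd.DataFrame,
                         frame_interval_min: float = 15.0
                         ) -> tuple[np.ndarray, np.ndarray]:
    durations, observed = [], []
    hours = frame_interval_min / 60.0
    for _, sub in tracks.groupby("cell_id", sort=True):
        sub = sub.sort_values("frame")
        death = sub.index[sub["event"] == "death"]
        if len(death):
            durations.append(float(sub.loc[death[0], "frame"]) * hours)
            observed.append(True)
        else:
            durations.append(float(sub["frame"].iloc[-1]) * hours)
            observed.append(False)
    return np.asarray(durations), np.asarray(observed)


def survival_curve(tracks: pd.DataFrame, group: Optional[str] = None,
                   frame_interval_min: float = 15.0
                   ) -> "SurvivalResult | dict[str, SurvivalResult]":
    """Kaplan-Meier survival of tracked cells, with the median ("half-life").

    ``tracks`` must carry a ``death`` event on the death frame of each dying
    cell; all other cells are right-censored at their last frame.  With
    ``group`` set, returns a dict of results keyed by that column's values.
    """
    if len(tracks) == 0:
        raise ValueError("empty track table")
    if group is not None:
        return {name: survival_curve(sub, None, frame_interval_min)
                for name, sub in tracks.groupby(group, sort=True)}
    durations, observed = _tracks_to_durations(tracks, frame_interval_min)
    kmf = KaplanMeierFitter()
    kmf.fit(durations, event_observed=observed)
    median = kmf.median_survival_time_
    ci = median_survival_times(kmf.confidence_interval_)
    lo, hi = float(ci.iloc[0, 0]), float(ci.iloc[0, 1])
    return SurvivalResult(
        times=kmf.survival_function_.index.to_numpy(dtype=float),
        survival=kmf.survival_function_.iloc[:, 0].to_numpy(dtype=float),
        half_life=float(median) if np.isfinite(median) else math.nan,
        half_life_ci=(lo, hi), n=len(durations), n_events=int(observed.sum()))


# ---------------------------------------------------------------------------
# ESC stratification

def epi_equivalents(n_esc: int, control_epi_range: tuple[int, int] = (5, 10)) -> str:
    """Dyadic stratum of an ESC compartment relative to the control epiblast.

    ``[5, 10] -> '1x'``, ``(10, 20] -> '2x'``, ``(20, 40] -> '4x'`` and so
    on; 0 is ``'control'`` and anything below the 1x floor is ``'<1x'``.
    """
    if n_esc < 0:
        raise ValueError("n_esc must be non-negative")
    lo, hi = control_epi_range
    if n_esc == 0:
        return "control"
    if n_esc < lo:
        return "<1x"
    mult = 1
    upper = hi
    while n_esc > upper:
        mult *= 2
        upper *= 2
    return f"{mult}x"
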