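"""Invasion-front quantification and the perpendicular-step-size sweep.

The invasion front in a direction sector is the mean distance beyond the
initial spheroid boundary of the m = 10 cells that travelled furthest into
that sector (8 sectors of 45 deg, centers at 0, 45, ..., 315; with flow
from top to bottom the downstream direction is 270 and upstream is 90).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import replace

import numpy as np
import pandas as pd

from .invasion import SimConfig, simulate_invasion

log = logging.getLogger(__name__)

SECTOR_CENTERS = np.arange(0, 360, 45)
DOWNSTREAM = 270
UPSTREAM = 90


def sector_front_distance(frame, center=(0.0, 0.0), radius0=150.0,
                          sectors=8, m=10):
    """Per-sector invasion-front distance for one frame of cell positions.

    For each sector: the mean of the m largest values of
    max(r - radius0, 0) among cells whose polar angle falls inside the
    sector. Ties are broken by cell index for determinism. Sectors holding
    fewer than m cells use all of them (flagged via logging); an empty
    sector reports 0.

    Returns a Series indexed by sector center (deg).
    """
    frame = np.asarray(frame, dtype=float)
    if frame.size == 0:
        raise ValueError("empty frame")
    cx, cy = center
    r = np.hypot(frame[:, 0] - cx, frame[:, 1] - cy)
    pol = np.degrees(np.arctan2(frame[:, 1] - cy, frame[:, 0] - cx)) % 360.0
    width = 360.0 / sectors
    centers = np.arange(sectors) * width
    dist = np.maximum(r - radius0, 0.0)
    out = {}
    for c in centers:
        delta = np.abs((pol - c + 180.0) % 360.0 - 180.0)
        sel = delta < width / 2.0
        # put the boundary (delta == width/2) in the counter-clockwise sector
        sel |= np.isclose(delta, width / 2.0) & (np.mod(pol - c, 360.0) < 180.0)
        vals = dist[sel]
        if vals.size == 0:
            log.warning("sector %s is empty; front set to 0", c)
            out[c] = 0.0
            continue
        if vals.size < m:
            log.warning("sector %s holds %d < m=%d cells; using all",
                        c, vals.size, m)
        idx = np.argsort(-vals, kind="stable")[:m]
        out[c] = float(vals[idx].mean())
    return pd.Series(out, name="front_um").rename_axis("sector_deg")


def front_table(cells, center=(0.0, 0.0), radius0=150.0, sectors=8, m=10):
    """SectorFrontTable: rows = recorded days, columns = sector centers."""
    rows = {}
    for t, fr in zip(cells.times, cells.frames):
        rows[float(t)] = sector_front_distance(fr, center, radius0, sectors, m)
    tab = pd.DataFrame(rows).T
    tab.index.name = "day"
    return tab


def relative_invasion(table, radius0):
    """Front distances normalized by the initial spheroid radius."""
    if radius0 == 0:
        raise ValueError("radius0 must be positive")
    return table / float(radius0)


def asymmetry_index(table, day=1.0):
    """Downstream/upstream front ratio at the given day."""
    row = table.loc[day]
    up = row[UPSTREAM]
    return float(row[DOWNSTREAM] / up) if up > 0 else np.inf


def sweep_perpendicular_step(base_config: SimConfig, grid,
                             r_v_list=(0.0, 60.0, 120.0, 220.0),
                             replicates=10, seed=0):
    """Replicate-averaged sector-front tables across perpendicular step sizes.

    Returns (tables, summary): ``tables`` maps r_v to the mean front table
    over ``replicates`` independent seeds; ``summary`` is a DataFrame with
    the day-1 downstream and upstream fronts and the asymmetry index
    (downstream/upstream at day 1, the calibration day) per r_v.
    """
    ss = np.random.SeedSequence(seed)
    rep_seeds = [int(s) for s in ss.generate_state(replicates)]
    tables = {}
    rows = []
    for r_v in r_v_list:
        reps = []
        for s in rep_seeds:
            cfg = replace(base_config, r_v=float(r_v), seed=s % (2**31 - 1))
            cells = simulate_invasion(cfg, grid)
            reps.append(front_table(cells, cfg.center, cfg.radius))
        mean_tab = sum(reps) / len(reps)
        tables[float(r_v)] = mean_tab
        rows.append({"r_v": float(r_v),
                     "downstream_day1": mean_tab.loc[1.0, DOWNSTREAM],
                     "upstream_day1": mean_tab.loc[1.0, UPSTREAM],
                     "asymmetry": asymmetry_index(mean_tab)})
    return tables, pd.DataFrame(rows).set_index("r_v")


def shape_mismatch(sim_table, reference_table):
    """RMS sector-wise front difference, averaged over days (um).

    Symmetric in its arguments; tables must share sectors and days.
    """
    a = np.asarray(sim_table, dtype=float)
    b = np.asarray(reference_table, dtype=float)
    if a.shape != b.shape:
        raise ValueError("tables have different shapes")
    per_day = np.sqrt(np.mean((a - b) ** 2, axis=-1))
    return float(np.mean(per_day))


def time_scaling_exponent(distances, days=None):
    """Least-squares slope of log(front) versus log(day).

    Non-positive distances are dropped with a warning; at least two
    positive points are required.
    """
    d = np.asarray(distances, dtype=float)
    t = np.arange(1, d.size + 1, dtype=float) if days is None \
        else np.asarray(days, dtype=float)
    ok = (d > 0) & (t > 0)
    if ok.sum() < d.size:
        warnings.warn("dropping non-positive points from the power-law fit")
    if ok.sum() < 2:
        raise ValueError("need at least two positive (day, distance) points")
    slope = np.polyfit(np.log(t[ok]), np.log(d[ok]), 1)[0]
    return float(slope)
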