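"""Behavioral read-outs: escape latencies, region occupancy, strategy
selection rates, responder classification, and the nonparametric tests.

All aggregations are returned as tidy pandas DataFrames (one row per
repeat x cell) so they can be written straight to CSV.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .arena import Region, PlatformSpec, in_region_mask
from .experiments import ExperimentResult, TrialRecord


# ---------------------------------------------------------------------------
# Latency
# ---------------------------------------------------------------------------

def escape_latencies(result: ExperimentResult,
                     grouping: str = "trial") -> pd.DataFrame:
    """Tidy latency table.

    grouping: "trial" (one row per repeat x trial), "session" (mean latency
    per repeat x session) or "first_fourth" (trial-1 and trial-4 latencies
    per repeat x session).
    """
    rows = []
    for rep, records in enumerate(result.records):
        for rec in records:
            rows.append((rep, rec.session, rec.trial, rec.index, rec.tag,
                         rec.latency, rec.guided))
    df = pd.DataFrame(rows, columns=["repeat", "session", "trial", "index",
                                     "tag", "latency", "guided"])
    if grouping == "trial":
        return df
    if grouping == "session":
        return (df.groupby(["repeat", "session"], as_index=False)["latency"]
                .mean())
    if grouping == "first_fourth":
        sub = df[df["trial"].isin([1, 4])]
        return sub.pivot_table(index=["repeat", "session"], columns="trial",
                               values="latency").rename(
            columns={1: "first", 4: "fourth"}).reset_index()
    raise ValueError(f"unknown grouping {grouping!r}")


# ---------------------------------------------------------------------------
# Occupancy
# ---------------------------------------------------------------------------

@dataclass
class OccupancyStat:
    fraction: float
    n_steps: int
    empty: bool = False    # phase window empty (reference region never entered)


def occupancy_rate(record: TrialRecord, region: Region, phase: str = "full",
                   reference: Region | None = None) -> OccupancyStat:
    """Fraction of the trial's timesteps spent inside ``region``.

    phase "before"/"after" restricts to the window before/after the first
    entry into ``reference`` (default: the region itself).  The two windows
    partition the trial; if the reference region is never entered the
    "before" window is the whole trial and "after" is empty (fraction 0,
    flagged).
    """
    xy = record.xy
    total = len(xy)
    if total == 0:
        return OccupancyStat(0.0, 0, empty=True)
    inside = in_region_mask(xy, region)
    if phase == "full":
        return OccupancyStat(float(inside.mean()), total)
    ref = reference if reference is not None else region
    ref_inside = inside if reference is None else in_region_mask(xy, ref)
    hits = np.nonzero(ref_inside)[0]
    first = int(hits[0]) if hits.size else total
    if phase == "before":
        if first == 0:
            return OccupancyStat(0.0, 0, empty=True)
        w = inside[:first]
        return OccupancyStat(float(w.mean()), first)
    if phase == "after":
        if first >= total:
            return OccupancyStat(0.0, 0, empty=True)
        w = inside[first:]
        return OccupancyStat(float(w.mean()), total - first)
    raise ValueError(f"unknown phase {phase!r}")


def occupancy_table(result: ExperimentResult, region_of, tags: set[str],
                    phase: str = "full", reference_of=None) -> pd.DataFrame:
    """Per repeat x trial occupancy for the trials matching ``tags``.

    ``region_of`` maps a TrialRecord to its Region (so that e.g. the octant
    can follow the rotated cue); ``reference_of`` likewise for the phase
    reference.
    """
    rows = []
    for rep, records in enumerate(result.records):
        for rec in records:
            if rec.tag not in tags:
                continue
            region = region_of(rec)
            ref = reference_of(rec) if reference_of is not None else None
            st = occupancy_rate(rec, region, phase, ref)
            rows.append((rep, rec.session, rec.trial, rec.tag,
                         rec.gradient_angle, st.fraction, st.n_steps, st.empty))
    return pd.DataFrame(rows, columns=["repeat", "session", "trial", "tag",
                                       "gradient_angle", "fraction", "n_steps",
                                       "empty"])


# ---------------------------------------------------------------------------
# Selection rates
# ---------------------------------------------------------------------------

def selection_rates(result: ExperimentResult, grouping: str = "session",
                    tags: set[str] | None = None,
                    sessions: set[int] | None = None) -> pd.DataFrame:
    """Fraction of executed timesteps per module, per repeat x grouping cell.

    grouping: "session", "tag", or "total".  Guided timesteps are excluded
    (only free, module-selected movement counts).  Rates over the registered
    modules sum to 1 within each cell.
    """
    nmod = len(result.module_names)
    rows = []
    for rep, records in enumerate(result.records):
        cells: dict = {}
        for rec in records:
            if tags is not None and rec.tag not in tags:
                continue
            if sessions is not None and rec.session not in sessions:
                continue
            if grouping == "session":
                key = rec.session
            elif grouping == "tag":
                key = rec.tag
            elif grouping == "total":
                key = "total"
            else:
                raise ValueError(f"unknown grouping {grouping!r}")
            counts = cells.setdefault(key, np.zeros(nmod, dtype=np.int64))
            if len(rec.selected):
                counts += np.bincount(rec.selected, minlength=nmod)
        for key, counts in cells.items():
            total = counts.sum()
            for k in range(nmod):
                rate = counts[k] / total if total else np.nan
                rows.append((rep, key, result.module_names[k],
                             result.module_kinds[k], rate, total))
    return pd.DataFrame(rows, columns=["repeat", "cell", "module", "kind",
                                       "rate", "n_steps"])


def kind_rate(df: pd.DataFrame, kind: str) -> pd.Series:
    """Per-repeat selection rate summed over the modules of one kind."""
    sub = df[df["kind"] == kind]
    return sub.groupby("repeat")["rate"].sum()


def selection_rate_in_window(result: ExperimentResult, kind: str,
                             window_of) -> np.ndarray:
    """Per-repeat selection rate of a module kind inside per-trial windows.

    ``window_of`` maps a TrialRecord to a boolean mask over its timesteps (or
    None to skip the trial).  Repeats whose windows are all empty yield NaN.
    """
    kidx = [i for i, k in enumerate(result.module_kinds) if k == kind]
    out = []
    for records in result.records:
        hit = tot = 0
        for rec in records:
            mask = window_of(rec)
            if mask is None:
                continue
            selw = rec.selected[mask]
            tot += len(selw)
            hit += int(np.isin(selw, kidx).sum())
        out.append(hit / tot if tot else np.nan)
    return np.asarray(out)


# ---------------------------------------------------------------------------
# Responder classification
# ---------------------------------------------------------------------------

def classify_responders(result: ExperimentResult, old_zone: Region,
                        new_platform: PlatformSpec,
                        tag: str = "competition") -> list[str]:
    """Label each repeat "place" or "cue" from its competition trial.

    A place-responder's competition trajectory enters the previous-platform
    zone before first reaching the new platform; everyone else followed the
    displaced cue directly.
    """
    labels = []
    for records in result.records:
        comp = [r for r in records if r.tag == tag]
        if not comp:
            raise ValueError("no competition-trial record in result")
        rec = comp[-1]
        in_old = in_region_mask(rec.xy, old_zone)
        first_old = np.nonzero(in_old)[0]
        labels.append("place" if first_old.size else "cue")
    return labels


# ---------------------------------------------------------------------------
# Nonparametric tests
# ---------------------------------------------------------------------------

def mann_whitney_u(sample_a, sample_b) -> tuple[float, float]:
    """Rank-sum U and two-sided p for two independent samples.

    Exact enumeration p when both samples are small (n_a * n_b <= 400) and
    tie-free; otherwise the tie-corrected normal approximation.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    ties = len(np.unique(np.concatenate([a, b]))) < a.size + b.size
    method = "exact" if (a.size * b.size <= 400 and not ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def wilcoxon_signed_rank(paired_a, paired_b) -> tuple[float, float]:
    """Signed-rank W and two-sided p for paired samples (zeros dropped).

    Exact p for n <= 12 tie-free nonzero differences, else the normal
    approximation.  All-zero differences are an error (test undefined).
    """
    a = np.asarray(paired_a, dtype=float)
    b = np.asarray(paired_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    d = a - b
    d = d[d != 0]
    if d.size == 0:
        raise ValueError("all differences are zero: test undefined")
    ties = len(np.unique(np.abs(d))) < d.size
    method = "exact" if (d.size <= 12 and not ties) else "approx"
    res = stats.wilcoxon(d, alternative="two-sided", mode=method,
                         zero_method="wilcox")
    return float(res.statistic), float(min(res.pvalue, 1.0))


def per_trial_selection_rate(result: ExperimentResult, kind: str,
                             sessions: set[int] | None = None) -> np.ndarray:
    """Per-repeat selection rate of a module kind, each trial weighted equally.

    Averaging per trial (rather than per timestep) keeps long early trials
    from dominating a stage-level rate.  Returns one value per repeat.
    """
    kidx = [i for i, k in enumerate(result.module_kinds) if k == kind]
    out = []
    for records in result.records:
        vals = [float(np.isin(rec.selected, kidx).mean())
                for rec in records
                if (sessions is None or rec.session in sessions)
                and len(rec.selected)]
        out.append(np.mean(vals) if vals else np.nan)
    return np.asarray(out)


def octant_b_occupancy(result: ExperimentResult,
                       burn_in: int = 0) -> pd.DataFrame:
    """Occupancy of the (rotated) proximal-cue octant in gradient trials.

    One row per repeat x gradient trial; the octant follows the rotated cue
    position recorded in the protocol metadata.  ``burn_in`` drops the first
    timesteps (release-point transit) from the window.
    """
    b0 = result.protocol_meta["b_angle"]
    rot = result.protocol_meta["rot_dir"]
    rows = []
    for rep, records in enumerate(result.records):
        for rec in records:
            if rec.tag != "gradient":
                continue
            region = Region.octant(b0 + math.radians(rot * rec.gradient_angle))
            frac = float(in_region_mask(rec.xy, region)[burn_in:].mean())
            rows.append((rep, rec.gradient_angle, frac))
    return pd.DataFrame(rows, columns=["repeat", "angle", "fraction"])


def f_octant_extinction(result: ExperimentResult) -> pd.Series:
    """Per-repeat occupancy of the distal cue F's octant in extinction trials."""
    region = Region.octant(result.protocol_meta["f_angle"])
    df = occupancy_table(result, lambda rec: region, {"extinction"})
    return df.groupby("repeat")["fraction"].mean()


def goal_quadrant_occupancy(result: ExperimentResult) -> pd.Series:
    """Per-repeat occupancy of the previous-platform quadrant in the
    blocking experiment's final (platform-less) test trial."""
    region = Region.quadrant(result.protocol_meta["goal_angle"])
    df = occupancy_table(result, lambda rec: region, {"test"})
    return df.groupby("repeat")["fraction"].mean()


def planning_rate_before_goal_quadrant(result: ExperimentResult) -> np.ndarray:
    """Per-repeat Planning selection rate during the test trial restricted to
    timesteps before the first entry into the goal quadrant (repeats whose
    window is empty are dropped)."""
    region = Region.quadrant(result.protocol_meta["goal_angle"])
    kidx = [i for i, k in enumerate(result.module_kinds) if k == "planning"]
    vals = []
    for records in result.records:
        recs = [r for r in records if r.tag == "test"]
        if not recs:
            raise ValueError("no test-trial record in result")
        rec = recs[0]
        inside = in_region_mask(rec.xy, region)
        hits = np.nonzero(inside)[0]
        first = int(hits[0]) if hits.size else len(rec.xy)
        if first > 0:
            vals.append(float(np.isin(rec.selected[:first], kidx).mean()))
    return np.asarray(vals)


def stars(p: float) -> str:
    """Significance stars: * p<0.05, ** p<0.01, *** p<0.001."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""
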