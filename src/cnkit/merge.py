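"""Cross-sample CNV merging into copy-number events (CNVEs).

Calls of the same type (losses and gains separately) are merged by iterative
50% reciprocal-overlap closure, realized as the connected components of the
graph whose edges join call pairs sharing at least 50% of their length in both
directions. Event bounds are then tightened 80% of the way from the innermost
member bound toward the outermost, and binomial carrier frequencies with
standard errors are attached.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .baits import BaitMap

__all__ = [
    "reciprocal_overlap",
    "merge_events",
    "adjust_boundaries",
    "event_frequencies",
    "bait_frequencies",
    "gene_overlap_annotation",
]


def reciprocal_overlap(a: tuple[int, int], b: tuple[int, int]) -> tuple[float, float]:
    """Overlap length divided by each interval's own length; (0, 0) if disjoint."""
    ov = min(a[1], b[1]) - max(a[0], b[0])
    if ov <= 0:
        return (0.0, 0.0)
    return (ov / (a[1] - a[0]), ov / (b[1] - b[0]))


class _DSU:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


def adjust_boundaries(starts, ends) -> tuple[int, int]:
    """Move each bound 80% of the way from the innermost member bound toward
    the outermost, rounding to the nearest integer."""
    starts = np.asarray(starts)
    ends = np.asarray(ends)
    inner_s, outer_s = starts.max(), starts.min()
    inner_e, outer_e = ends.min(), ends.max()
    new_s = int(np.rint(inner_s + 0.8 * (outer_s - inner_s)))
    new_e = int(np.rint(inner_e + 0.8 * (outer_e - inner_e)))
    return new_s, new_e


def merge_events(calls: pd.DataFrame, min_ro: float = 0.5) -> tuple[pd.DataFrame, np.ndarray]:
    """Merge all samples' calls into events; losses and gains separately.

    Parameters
    ----------
    calls
        One row per call with columns sample_id, chrom, start, end, state.
    min_ro
        Both overlap fractions of an edge must reach this value.

    Returns
    -------
    (events, assignment): events table with one row per CNVE (columns chrom,
    start, end, type, n_calls, n_carriers and the member call index list) and
    an integer array giving each input call's event index (order-free: the
    partition does not depend on the input row order).
    """
    calls = calls.reset_index(drop=True)
    n = len(calls)
    dsu = _DSU(n)
    for (state, chrom), grp in calls.groupby(["state", "chrom"], sort=True):
        idx = grp.index.to_numpy()
        order = idx[np.lexsort((grp["end"].to_numpy(), grp["start"].to_numpy()))]
        starts = calls.loc[order, "start"].to_numpy()
        ends = calls.loc[order, "end"].to_numpy()
        active: list[int] = []
        for k in range(len(order)):
            s, e = starts[k], ends[k]
            active = [a for a in active if ends[a] > s]
            for a in active:
                ro = reciprocal_overlap((starts[a], ends[a]), (s, e))
                if min(ro) >= min_ro:
                    dsu.union(int(order[a]), int(order[k]))
            active.append(k)

    roots = np.array([dsu.find(i) for i in range(n)])
    event_rows = []
    assignment = np.full(n, -1, dtype=int)
    # deterministic event order: by (chrom order in data, start, type)
    comp_members: dict[int, list[int]] = {}
    for i, r in enumerate(roots):
        comp_members.setdefault(r, []).append(i)
    comps = sorted(
        comp_members.values(),
        key=lambda m: (
            str(calls.loc[m[0], "chrom"]),
            int(calls.loc[m, "start"].min()),
            int(calls.loc[m, "end"].max()),
            str(calls.loc[m[0], "state"]),
        ),
    )
    for eid, members in enumerate(comps):
        sub = calls.loc[members]
        start, end = adjust_boundaries(sub["start"].to_numpy(), sub["end"].to_numpy())
        event_rows.append(
            {
                "event_id": eid,
                "chrom": sub["chrom"].iloc[0],
                "start": start,
                "end": end,
                "type": sub["state"].iloc[0],
                "n_calls": len(members),
                "n_carriers": sub["sample_id"].nunique(),
                "members": list(members),
            }
        )
        assignment[members] = eid
    events = pd.DataFrame(
        event_rows,
        columns=["event_id", "chrom", "start", "end", "type",
                 "n_calls", "n_carriers", "members"],
    )
    return events, assignment


def _binom_se(p: float, n: int) -> float:
    return float(np.sqrt(p * (1.0 - p) / n)) if n > 0 else 0.0


def event_frequencies(
    events: pd.DataFrame,
    assignment: np.ndarray,
    calls: pd.DataFrame,
    n_samples: int,
) -> pd.DataFrame:
    """Attach loss/gain/overall carrier frequencies and binomial SEs.

    A sample counts once per event even with several member calls; the
    overall frequency counts samples carrying a call of either type that
    reciprocally overlaps (>=50%) the event's adjusted span.
    """
    calls = calls.reset_index(drop=True)
    out = events.copy()
    freq_loss, freq_gain, freq_all = [], [], []
    se_loss, se_gain, se_all = [], [], []
    by_chrom = {c: g for c, g in calls.groupby("chrom")}
    for _, ev in events.iterrows():
        members = ev["members"]
        carriers = set(calls.loc[members, "sample_id"])
        p_own = len(carriers) / n_samples
        # samples with any call of either type reciprocally overlapping the locus
        locus = (ev["start"], ev["end"])
        near = by_chrom.get(ev["chrom"])
        all_carriers = set()
        if near is not None:
            for sid, s, e in zip(near["sample_id"], near["start"], near["end"]):
                ro = reciprocal_overlap(locus, (s, e))
                if min(ro) >= 0.5:
                    all_carriers.add(sid)
        all_carriers |= carriers
        p_all = len(all_carriers) / n_samples
        if ev["type"] == "loss":
            fl, fg = p_own, 0.0
        else:
            fl, fg = 0.0, p_own
        freq_loss.append(fl)
        freq_gain.append(fg)
        freq_all.append(p_all)
        se_loss.append(_binom_se(fl, n_samples) if ev["type"] == "loss" else 0.0)
        se_gain.append(_binom_se(fg, n_samples) if ev["type"] == "gain" else 0.0)
        se_all.append(_binom_se(p_all, n_samples))
    out["freq_loss"] = freq_loss
    out["freq_gain"] = freq_gain
    out["freq_all"] = freq_all
    out["se_loss"] = se_loss
    out["se_gain"] = se_gain
    out["se_all"] = se_all
    return out


def bait_frequencies(
    calls: pd.DataFrame, bait_map: BaitMap, n_samples: int
) -> pd.DataFrame:
    """Per bait: fraction of samples with >=1 overlapping call, by type and overall."""
    sample_index = {s: i for i, s in enumerate(pd.unique(calls["sample_id"]))}
    n_known = max(len(sample_index), 1)
    covered = {
        "loss": np.zeros((n_known, len(bait_map)), dtype=bool),
        "gain": np.zeros((n_known, len(bait_map)), dtype=bool),
    }
    slices = bait_map.chrom_slices()
    starts, ends = bait_map.start, bait_map.end
    for sid, chrom, s, e, state in zip(
        calls["sample_id"], calls["chrom"], calls["start"], calls["end"], calls["state"]
    ):
        sl = slices.get(chrom)
        if sl is None:
            continue
        lo = sl.start + np.searchsorted(ends[sl], s, side="right")
        hi = sl.start + np.searchsorted(starts[sl], e, side="left")
        if hi > lo:
            covered[state][sample_index[sid], lo:hi] = True
    either = covered["loss"] | covered["gain"]
    return pd.DataFrame(
        {
            "bait_id": bait_map.bait_id,
            "freq_loss": covered["loss"].sum(axis=0) / n_samples,
            "freq_gain": covered["gain"].sum(axis=0) / n_samples,
            "freq_all": either.sum(axis=0) / n_samples,
        }
    )


def gene_overlap_annotation(
    calls: pd.DataFrame, genes: pd.DataFrame, min_ro: float = 0.5
) -> pd.DataFrame:
    """(call, gene) pairs whose spans reciprocally overlap by >= min_ro.

    ``genes`` needs columns chrom, start, end, gene_id.
    """
    rows = []
    calls = calls.reset_index(drop=True)
    by_chrom = {c: g for c, g in genes.groupby("chrom")}
    for i, call in calls.iterrows():
        grp = by_chrom.get(call["chrom"])
        if grp is None:
            continue
        for _, gene in grp.iterrows():
            ro = reciprocal_overlap(
                (call["start"], call["end"]), (gene["start"], gene["end"])
            )
            if min(ro) >= min_ro:
                rows.append(
                    {
                        "call_index": i,
                        "sample_id": call["sample_id"],
                        "chrom": call["chrom"],
                        "start": call["start"],
                        "end": call["end"],
                        "state": call["state"],
                        "gene_id": gene["gene_id"],
                        "ro_call": ro[0],
                        "ro_gene": ro[1],
                    }
                )
    return pd.DataFrame(
        rows,
        columns=["call_index", "sample_id", "chrom", "start", "end",
                 "state", "gene_id", "ro_call", "ro_gene"],
    )
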