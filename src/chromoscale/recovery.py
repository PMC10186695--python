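"""Scoring of calls against planted ground truth (synthetic runs only)."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .compartments import CompartmentProfile
from .genome import BinnedGenome
from .synthetic import GroundTruth

__all__ = [
    "label_recovery",
    "switch_jaccard",
    "boundary_recovery",
    "loop_recovery",
    "lost_loop_recovery",
]


def _coarse_majority_labels(truth: GroundTruth, grid: BinnedGenome
                            ) -> dict[str, np.ndarray]:
    """Planted labels aggregated to a coarser grid by majority vote."""
    factor = grid.bin_size // truth.grid.bin_size
    out = {}
    for c in grid.chroms:
        fine = truth.compartment_labels[c]
        n2 = grid.n_bins(c)
        lab = np.empty(n2, dtype="<U1")
        for b in range(n2):
            chunk = fine[b * factor:(b + 1) * factor]
            lab[b] = "A" if (chunk == "A").sum() * 2 >= len(chunk) else "B"
        out[c] = lab
    return out


def label_recovery(profile: CompartmentProfile, truth: GroundTruth) -> float:
    """Fraction of unmasked profile bins whose A/B label matches the
    majority planted label."""
    planted = _coarse_majority_labels(truth, profile.grid)
    match = total = 0
    for c in profile.grid.chroms:
        called = profile.label(c)
        ok = called != "."
        match += int((called[ok] == planted[c][ok]).sum())
        total += int(ok.sum())
    return match / total if total else np.nan


def switch_jaccard(categories: dict[str, np.ndarray], truth_2: GroundTruth
                   ) -> float:
    """Bin-level Jaccard between called switched bins (A-to-B or B-to-A at
    the calling resolution) and the planted switch mask."""
    changes = truth_2.changes
    inter = union = 0
    for c, cat in categories.items():
        factor = len(changes.switched_bins[c]) // len(cat)
        planted_fine = changes.switched_bins[c]
        n2 = len(cat)
        planted = np.array([
            planted_fine[b * factor:(b + 1) * factor].sum() * 2
            >= len(planted_fine[b * factor:(b + 1) * factor])
            for b in range(n2)])
        called = np.isin(cat, ["A-to-B", "B-to-A"])
        assessed = cat != "masked"
        inter += int((planted & called & assessed).sum())
        union += int(((planted | called) & assessed).sum())
    return inter / union if union else np.nan


def _greedy_match(called: np.ndarray, truth: np.ndarray, tol: int
                  ) -> int:
    used = np.zeros(len(truth), dtype=bool)
    n = 0
    for b in np.sort(called):
        cand = np.flatnonzero(~used & (np.abs(truth - b) <= tol))
        if len(cand):
            j = cand[np.argmin(np.abs(truth[cand] - b))]
            used[j] = True
            n += 1
    return n


def boundary_recovery(called_bins: dict[str, np.ndarray],
                      truth_boundaries: dict[str, np.ndarray],
                      tol_bins: int = 2) -> dict[str, float]:
    """Recall and precision of boundary calls against planted boundaries
    (one-to-one matching within +/- tol_bins)."""
    n_match = n_called = n_truth = 0
    for c, truth in truth_boundaries.items():
        called = np.asarray(called_bins.get(c, []), dtype=int)
        n_match += _greedy_match(called, np.asarray(truth), tol_bins)
        n_called += len(called)
        n_truth += len(truth)
    return {
        "recall": n_match / n_truth if n_truth else np.nan,
        "precision": n_match / n_called if n_called else np.nan,
        "n_called": n_called,
        "n_truth": n_truth,
    }


def _loop_midpoints(table: pd.DataFrame):
    return (table["chrom"].to_numpy(),
            ((table["start1"] + table["end1"]) // 2).to_numpy(),
            ((table["start2"] + table["end2"]) // 2).to_numpy())


def loop_recovery(loop_table: pd.DataFrame, truth_loops: list[tuple],
                  grid: BinnedGenome, tol_bp: int = 15_000
                  ) -> dict[str, float]:
    """Recall/precision of called loops against planted anchor bin pairs
    (Chebyshev match of anchor midpoints within tol_bp)."""
    bs = grid.bin_size
    truth = [(c, bi * bs + bs // 2, bj * bs + bs // 2)
             for c, bi, bj in truth_loops]
    used = np.zeros(len(truth), dtype=bool)
    n_match = 0
    if len(loop_table):
        chroms, m1, m2 = _loop_midpoints(loop_table)
        for c, a, b in zip(chroms, m1, m2):
            best, best_d = -1, tol_bp + 1
            for k, (tc, ta, tb) in enumerate(truth):
                if used[k] or tc != c:
                    continue
                d = max(abs(a - ta), abs(b - tb))
                if d <= tol_bp and d < best_d:
                    best, best_d = k, d
            if best >= 0:
                used[best] = True
                n_match += 1
    n_called = len(loop_table)
    return {
        "recall": n_match / len(truth) if truth else np.nan,
        "precision": n_match / n_called if n_called else np.nan,
        "n_called": n_called,
        "n_truth": len(truth),
    }


def lost_loop_recovery(diff: dict[str, pd.DataFrame], truth_2: GroundTruth,
                       tol_bp: int = 15_000) -> dict[str, float]:
    """Recall of planted lost loops among 'lost' differential calls, and
    the spurious-gained rate (gained calls not matching any planted gain,
    as a fraction of assessed union loops)."""
    grid = truth_2.grid
    lost = loop_recovery(diff["lost"], truth_2.changes.loops_lost, grid, tol_bp)
    gained = loop_recovery(diff["gained"], truth_2.changes.loops_gained,
                           grid, tol_bp)
    n_union = sum(len(diff[k]) for k in ("gained", "lost", "common"))
    n_spurious = len(diff["gained"]) - int(
        round(gained["recall"] * gained["n_truth"])) \
        if np.isfinite(gained.get("recall", np.nan)) else len(diff["gained"])
    return {
        "lost_recall": lost["recall"],
        "gained_recall": gained["recall"],
        "spurious_gained_fraction":
            n_spurious / n_union if n_union else np.nan,
        "n_union": n_union,
    }
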