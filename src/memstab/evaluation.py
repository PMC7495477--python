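"""Ranked-list performance: cumulative hit curves, baselines, success rates."""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd

log = logging.getLogger("memstab")


def enrichment_curve(ranked_positions, truth: dict) -> pd.DataFrame:
    """Cumulative percent of stabilisers found and running true-positive rate.

    ``ranked_positions`` is the ranked sequence of positions (best first);
    ``truth`` maps position to 'stabilising' / 'destabilising' / 'neutral'.
    Positions without a truth label are skipped (and logged).
    """
    total_hits = sum(1 for v in truth.values() if v == "stabilising")
    if total_hits == 0:
        raise ValueError("truth set contains no stabilisers")
    known = [p for p in ranked_positions if p in truth]
    skipped = len(list(ranked_positions)) - len(known)
    if skipped:
        log.info("enrichment curve: %d ranked positions lack truth labels", skipped)
    rows, hits = [], 0
    for r, pos in enumerate(known, start=1):
        hits += truth[pos] == "stabilising"
        rows.append({"rank": r, "position": pos,
                     "cumulative_percent": 100.0 * hits / total_hits,
                     "tpr": hits / r})
    return pd.DataFrame(rows)


def random_baseline(truth: dict, n_samplings: int = 10, sample_size: int = 100,
                    seed: int = 0) -> dict:
    """Stabiliser/destabiliser counts expected from random position picks.

    Draws ``n_samplings`` subsets of ``sample_size`` positions without
    replacement and reports the mean and SD of the per-sample counts.
    """
    positions = sorted(truth)
    if sample_size > len(positions):
        raise ValueError(
            f"sample_size {sample_size} exceeds truth set size {len(positions)}")
    rng = np.random.default_rng(seed)
    stab_counts, destab_counts = [], []
    for _ in range(n_samplings):
        picked = rng.choice(positions, size=sample_size, replace=False)
        labels = [truth[p] for p in picked]
        stab_counts.append(sum(lab == "stabilising" for lab in labels))
        destab_counts.append(sum(lab == "destabilising" for lab in labels))
    return {
        "stabilisers_mean": float(np.mean(stab_counts)),
        "stabilisers_sd": float(np.std(stab_counts, ddof=1)),
        "destabilisers_mean": float(np.mean(destab_counts)),
        "destabilisers_sd": float(np.std(destab_counts, ddof=1)),
        "n_samplings": n_samplings,
        "sample_size": sample_size,
    }


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def success_rate(statuses) -> dict:
    """Percent stabilising and destabilising among tested variants.

    Rounded to the nearest integer percent, half away from zero.
    """
    statuses = list(statuses)
    if not statuses:
        raise ValueError("no tested variants")
    n = len(statuses)
    stab = sum(s == "stabilising" for s in statuses)
    destab = sum(s == "destabilising" for s in statuses)
    return {
        "n_tested": n,
        "n_stabilising": stab,
        "n_destabilising": destab,
        "stabilising_percent": _round_half_away(100.0 * stab / n),
        "destabilising_percent": _round_half_away(100.0 * destab / n),
    }
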