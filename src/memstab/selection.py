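"""Merge ranked candidate lists into a final mutagenesis order sheet.

Selection proceeds in four steps: drop candidates at excluded positions
(residues known to be functionally critical), resolve positions proposed
by more than one module under a configurable overlap rule, truncate each
module's list to its top fraction of ranked sites, and fill per-module
quotas round-robin by rank.  Every dropped candidate is kept in the report
with its reason, so the final sheet is auditable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .evidence import CandidateList

log = logging.getLogger("memstab")

OVERLAP_RULES = ("highest_score_wins", "drop_identical_substitution_only",
                 "allow_all")

#: Priority when two modules tie on score for the same position.
MODULE_PRIORITY = ("data_driven", "model_based", "deep_sequence")

DROP_REASONS = ("excluded_position", "overlap", "below_fraction", "over_quota")


@dataclass
class SelectionPolicy:
    """How the per-module ranked lists are merged.

    top_fraction: percent of each module's ranked sites considered.
    per_module_quota: cap on candidates taken per module (None = no cap).
    overlap_rule: how positions proposed by several modules are resolved.
    exclusions: 1-based positions barred from mutagenesis.
    """

    top_fraction: float = 100.0
    per_module_quota: int | None = None
    overlap_rule: str = "highest_score_wins"
    exclusions: frozenset[int] = field(default_factory=frozenset)

    def __post_init__(self):
        if not 0 < self.top_fraction <= 100:
            raise ValueError(f"top_fraction {self.top_fraction} outside (0, 100]")
        if self.per_module_quota is not None and self.per_module_quota < 1:
            raise ValueError("per_module_quota must be >= 1 when set")
        if self.overlap_rule not in OVERLAP_RULES:
            raise ValueError(f"unknown overlap rule {self.overlap_rule!r}")
        self.exclusions = frozenset(int(p) for p in self.exclusions)


def _pool(candidate_lists: list[CandidateList]) -> pd.DataFrame:
    frames = []
    for cl in candidate_lists:
        t = cl.table.copy()
        t.insert(0, "module", cl.module)
        frames.append(t)
    df = pd.concat(frames, ignore_index=True)
    # Identical (position, substitution) proposed by two modules collapses to
    # the higher-scoring module's entry under any rule.
    df = df.sort_values("normalised_score", ascending=False, kind="mergesort")
    df = df.drop_duplicates(subset=["position", "mut_aa"], keep="first")
    return df.reset_index(drop=True)


def apply_exclusions(candidates: pd.DataFrame,
                     exclusions: frozenset[int]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split candidates into (kept, dropped-at-excluded-position)."""
    mask = candidates["position"].isin(exclusions)
    dropped = candidates[mask].copy()
    dropped["drop_reason"] = "excluded_position"
    log.info("exclusion lists removed %d of %d candidates",
             len(dropped), len(candidates))
    return candidates[~mask].copy(), dropped


def resolve_overlaps(candidates: pd.DataFrame, rule: str,
                     ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Resolve positions proposed by more than one module.

    highest_score_wins: one candidate per position (max normalised score;
    ties broken by module priority, then substitution alphabetically).
    drop_identical_substitution_only: different substitutions at the same
    site may coexist (identical ones were already collapsed in pooling).
    allow_all: nothing dropped.
    """
    if rule not in OVERLAP_RULES:
        raise ValueError(f"unknown overlap rule {rule!r}")
    if rule in ("allow_all", "drop_identical_substitution_only"):
        return candidates.copy(), candidates.iloc[0:0].assign(drop_reason=[])
    prio = {m: i for i, m in enumerate(MODULE_PRIORITY)}
    ordered = candidates.assign(_prio=candidates["module"].map(prio)).sort_values(
        by=["normalised_score", "_prio", "mut_aa"],
        ascending=[False, True, True], kind="mergesort")
    keep_mask = ~ordered.duplicated(subset="position", keep="first")
    kept = ordered[keep_mask].drop(columns="_prio")
    dropped = ordered[~keep_mask].drop(columns="_prio").copy()
    dropped["drop_reason"] = "overlap"
    log.info("overlap resolution (%s) removed %d candidates", rule, len(dropped))
    return kept, dropped


def finalise_selection(candidate_lists: list[CandidateList],
                       policy: SelectionPolicy,
                       ranked_sites_per_module: dict[str, int] | None = None,
                       ) -> "SelectionReport":
    """Run the full merge and return kept + dropped tables.

    ``ranked_sites_per_module`` gives the number of sites each module
    ranked (defaults to that module's list length); the top-fraction cut
    keeps each module's candidates with rank <= fraction of that count.
    """
    pooled = _pool(candidate_lists)
    kept, drop_excl = apply_exclusions(pooled, policy.exclusions)
    kept, drop_over = resolve_overlaps(kept, policy.overlap_rule)

    sizes = {cl.module: len(cl) for cl in candidate_lists}
    if ranked_sites_per_module:
        sizes.update(ranked_sites_per_module)
    limits = {m: max(1, int(n * policy.top_fraction / 100.0))
              for m, n in sizes.items()}
    below = kept["rank"] > kept["module"].map(limits)
    drop_frac = kept[below].copy()
    drop_frac["drop_reason"] = "below_fraction"
    kept = kept[~below]

    drop_quota = kept.iloc[0:0].assign(drop_reason=[])
    if policy.per_module_quota is not None:
        frames_keep, frames_drop = [], []
        for module, group in kept.groupby("module", sort=True):
            group = group.sort_values("rank", kind="mergesort")
            if len(group) < policy.per_module_quota:
                log.warning("module %s: quota %d exceeds %d surviving candidates;"
                            " taking all", module, policy.per_module_quota,
                            len(group))
            frames_keep.append(group.iloc[:policy.per_module_quota])
            frames_drop.append(group.iloc[policy.per_module_quota:])
        kept = pd.concat(frames_keep, ignore_index=True)
        drop_quota = pd.concat(frames_drop, ignore_index=True)
        if len(drop_quota):
            drop_quota["drop_reason"] = "over_quota"

    kept = kept.sort_values(["module", "rank"], kind="mergesort").reset_index(drop=True)
    dropped = pd.concat([drop_excl, drop_over, drop_frac, drop_quota],
                        ignore_index=True)
    return SelectionReport(kept, dropped, policy)


@dataclass
class SelectionReport:
    kept: pd.DataFrame
    dropped: pd.DataFrame
    policy: SelectionPolicy

    def __post_init__(self):
        bad = set(self.dropped.get("drop_reason", pd.Series(dtype=str))) - set(DROP_REASONS)
        if bad:
            raise ValueError(f"unknown drop reasons {bad}")
        if self.kept["position"].isin(self.policy.exclusions).any():
            raise AssertionError("kept candidate at an excluded position")

    def order_sheet(self) -> pd.DataFrame:
        """Final table sorted by (module, rank), labelled for ordering."""
        out = self.kept.copy()
        out["variant"] = [f"{r.wt_aa}{int(r.position)}{r.mut_aa}"
                          for r in out.itertuples()]
        cols = ["module", "variant", "position", "wt_aa", "mut_aa",
                "raw_score", "normalised_score", "rank"]
        return out[cols]

    def write(self, selection_path, report_path=None) -> None:
        self.order_sheet().to_csv(selection_path, sep="\t", index=False,
                                  float_format="%.6g")
        if report_path is not None:
            self.dropped.to_csv(report_path, sep="\t", index=False,
                                float_format="%.6g")
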